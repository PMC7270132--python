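"""Independent, deliberately naive transcription of the model equations.

Each state derivative is written out term by term on plain dictionaries,
with no shared sub-expressions and no dependency on the package's own
right-hand side. Used only as a cross-checking oracle in tests.
"""

import math


def literal_derivatives(s: dict, p: dict, cx_active: bool) -> dict:
    """dX/dt for every state, straight off the equations, one term at a time."""
    d = {}

    # ADPC: proliferation - death - mutation - CTL killing - NK killing
    d["X1"] = (p["r_p1"] * s["A"] * s["X1"]
               - p["mu_1"] * (1 - s["A"]) * s["X1"]
               - p["r_M"] * (1 - s["A"]) * s["X1"]
               - p["k_CX"] * (1 + p["delta_ICB"] * s["I_CB"]) * s["C2"] * s["X1"]
               - p["k_NX"] * (math.exp(-p["k_RN"] * s["R2"])
                              + math.exp(-p["k_MN"] * s["M"])) * s["N"] * s["X1"])

    # AIPC: proliferation - death + mutation - CTL killing - NK killing
    d["X2"] = (p["r_p2"] * s["X2"]
               - p["mu_2"] * s["X2"]
               + p["r_M"] * (1 - s["A"]) * s["X1"]
               - p["k_CX"] * (1 + p["delta_ICB"] * s["I_CB"]) * s["C2"] * s["X2"]
               - p["k_NX"] * (math.exp(-p["k_RN"] * s["R2"])
                              + math.exp(-p["k_MN"] * s["M"])) * s["N"] * s["X2"])

    # mature DC: vaccine + recruitment over tumor apoptosis - migration
    d["Dm"] = (p["a_VD"] * s["V"]
               + p["a_XD"] * (p["mu_1"] * (1 - s["A"]) * s["X1"]
                              + p["mu_2"] * s["X2"]
                              + p["k_CX"] * (1 + p["delta_ICB"] * s["I_CB"])
                              * s["C2"] * (s["X1"] + s["X2"])
                              + p["k_NX"] * (math.exp(-p["k_RN"] * s["R2"])
                                             + math.exp(-p["k_MN"] * s["M"]))
                              * s["N"] * (s["X1"] + s["X2"]))
               - p["m_D"] * s["Dm"])

    # prostate CTL: activation + IL-2 stimulation + migration - inhibition - death
    d["C2"] = (p["a_DC"] * s["Dm"]
               + p["a_IC"] * s["C2"] * s["I2"] / (p["s_I"] + s["I2"])
               + p["p_C"] * p["m_C"] * s["C1"]
               - p["k_RC"] * s["R2"] * s["C2"]
               - p["k_MC"] * s["M"] * s["C2"]
               - p["mu_C"] * s["C2"])

    # NK: source - death - tumor-contact inactivation + IL-2 stimulation
    d["N"] = (p["rho_N"]
              - p["mu_N"] * s["N"]
              - p["k_XN"] * s["N"] * (s["X1"] + s["X2"])
              + p["a_IN"] * s["N"] * s["I2"] / (p["s_N"] + s["I2"]))

    # prostate Treg
    d["R2"] = (p["a_DR"] * s["Dm"]
               + p["a_IR"] * s["I2"]
               + p["p_R"] * p["m_R"] * s["R1"]
               + p["a_XR"] * (s["X1"] + s["X2"])
               - p["mu_R"] * s["R2"]
               - p["k_antiRR"] * s["anti_R"] * s["R2"])

    # MDSC: source - death + saturating tumor activation - drug kill
    d["M"] = (p["rho_M"]
              - p["mu_M"] * s["M"]
              + p["a_XM"] * (s["X1"] + s["X2"]) / (p["s_M"] + s["X1"] + s["X2"])
              - p["k_antiMM"] * s["anti_M"] * s["M"])

    # prostate IL-2
    d["I2"] = (p["a_CI"] * s["C2"]
               - p["mu_I"] * s["I2"]
               - p["k_antiI"] * s["anti_I"] * s["I2"])

    # androgen: homeostasis, minus deprivation forcing when castrated
    d["A"] = (p["lambda_A"] * (1 - s["A"])
              - p["lambda_A"] * (1.0 if cx_active else 0.0))

    # lymphoid dendritic cells
    d["Df"] = p["p_D"] * p["m_D"] * s["Dm"] - p["a_DfDr"] * s["Df"]
    d["Dr"] = p["a_DfDr"] * s["Df"] - p["mu_D"] * s["Dr"]

    # lymphoid CTL
    d["C1"] = (p["a_Df"] * s["Df"]
               + p["a_IC"] * s["C1"] * s["I1"] / (p["s_I"] + s["I1"])
               - p["m_C"] * s["C1"]
               - p["k_RC"] * s["R1"] * s["C1"]
               - p["mu_C"] * s["C1"])

    # lymphoid Treg
    d["R1"] = (p["a_DrR"] * s["Dr"]
               + p["a_IR"] * s["I1"]
               - p["m_R"] * s["R1"]
               - p["mu_R"] * s["R1"]
               - p["k_antiRR"] * s["anti_R"] * s["R1"])

    # lymphoid IL-2
    d["I1"] = (p["a_CI"] * s["C1"]
               - p["mu_I"] * s["I1"]
               - p["k_antiI"] * s["anti_I"] * s["I1"])

    # drug decays
    d["V"] = -p["lambda_V"] * s["V"]
    d["anti_I"] = -p["lambda_AI"] * s["anti_I"]
    d["anti_R"] = -p["lambda_AR"] * s["anti_R"]
    d["anti_M"] = -p["lambda_AM"] * s["anti_M"]
    d["I_CB"] = -p["lambda_ICB"] * s["I_CB"]
    return d
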