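{
  "_comment": "Synthetic nominal parameter set (per-day rates, fold-change units). Probabilities, half-lives, the NK allometry constants and the NK injection multiplier are literature values; the remaining rates are package-chosen nominals anchored to the model's qualitative behaviour, not a published calibration.",
  "r_p1": 0.06,
  "mu_1": 0.03,
  "r_M": 0.1,
  "k_CX": 0.05,
  "delta_ICB": 0.6,
  "k_NX": 0.021,
  "k_RN": 1.0,
  "k_MN": 1.0,
  "r_p2": 0.06,
  "mu_2": 0.02,
  "a_VD": 0.1,
  "a_XD": 1.0,
  "m_D": 0.3,
  "a_DC": 0.15,
  "a_IC": 0.1,
  "s_I": 1.0,
  "p_C": 0.5,
  "m_C": 0.1,
  "k_RC": 0.03,
  "k_MC": 0.2,
  "mu_C": 0.08,
  "k_XN": 0.1,
  "a_IN": 0.002,
  "s_N": 1.0,
  "a_DR": 0.05,
  "a_IR": 0.04,
  "p_R": 0.5,
  "m_R": 0.1,
  "a_XR": 0.03,
  "mu_R": 0.1,
  "k_antiRR": 0.5,
  "rho_M": 0.02,
  "mu_M": 0.08,
  "a_XM": 0.18,
  "s_M": 1.0,
  "k_antiMM": 0.6,
  "a_CI": 0.1,
  "mu_I": 0.1,
  "k_antiI": 1.0,
  "p_D": 0.5,
  "a_DfDr": 0.1,
  "mu_D": 0.2,
  "a_Df": 0.1,
  "a_DrR": 0.2,
  "t_half_A": 7.0,
  "t_half_V": 7.0,
  "t_half_AI": 7.0,
  "t_half_AR": 7.0,
  "t_half_AM": 0.14583333333333334,
  "t_half_ICB": 5.0,
  "K_nk": 0.0371,
  "m_mice": 0.029,
  "nk_injection_multiplier": 9.0,
  "invitro_tumor_0": 1.0,
  "invitro_nk_0": 10.0,
  "invitro_ctl_0": 1.0,
  "invitro_mdsc_0": 1.0
}
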