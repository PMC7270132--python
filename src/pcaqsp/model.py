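"""State vector and right-hand side of the 19-ODE tumor--immune model.

Two compartments are modelled. The prostate gland holds the two tumor
populations (androgen-dependent X1 and androgen-independent X2), mature
dendritic cells Dm, effector CTLs C2, NK cells N, Tregs R2, MDSCs M,
IL-2 I2 and the androgen level A. The lymphoid tissue holds functional and
regulatory dendritic cells Df/Dr, CTLs C1, Tregs R1 and IL-2 I1. Five more
variables track exponentially decaying drug levels: the dendritic-cell
vaccine V, anti-IL-2 ``anti_I``, anti-Treg ``anti_R``, anti-MDSC ``anti_M``
and the checkpoint-blockade cocktail ``I_CB``.

Every biological variable is a fold-change relative to its initial value,
so the untreated baseline is 1 (0 for the initially absent X2 and drugs).
Androgen deprivation is not a state variable: it is a boolean forcing term
(``cx_active``) that switches the androgen equation from homeostasis to
exponential decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .parameters import ParameterSet

__all__ = ["SystemState", "STATE_NAMES", "N_STATES", "compute_derivatives",
           "default_initial_state", "rhs"]

STATE_NAMES = (
    "X1", "X2", "Dm", "C2", "N", "R2", "M", "I2", "A",
    "Df", "Dr", "C1", "R1", "I1",
    "V", "anti_I", "anti_R", "anti_M", "I_CB",
)
N_STATES = len(STATE_NAMES)

#: Drug state variable per dosed therapy (CX and NK act through the castration
#: flag and the NK initial condition instead).
DRUG_STATE_OF_THERAPY = {"V": "V", "AI": "anti_I", "AR": "anti_R",
                         "AM": "anti_M", "ICB": "I_CB"}


@dataclass(frozen=True)
class SystemState:
    """One snapshot of the 19 state variables (fold-change units)."""

    X1: float = 1.0
    X2: float = 0.0
    Dm: float = 1.0
    C2: float = 1.0
    N: float = 1.0
    R2: float = 1.0
    M: float = 1.0
    I2: float = 1.0
    A: float = 1.0
    Df: float = 1.0
    Dr: float = 1.0
    C1: float = 1.0
    R1: float = 1.0
    I1: float = 1.0
    V: float = 0.0
    anti_I: float = 0.0
    anti_R: float = 0.0
    anti_M: float = 0.0
    I_CB: float = 0.0

    @property
    def total_tumor(self) -> float:
        return self.X1 + self.X2

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SystemState":
        y = np.asarray(y, dtype=float)
        if y.shape != (N_STATES,):
            raise ValueError(f"expected a length-{N_STATES} vector, got shape "
                             f"{y.shape}")
        return cls(**dict(zip(STATE_NAMES, map(float, y))))

    def replace(self, **changes: float) -> "SystemState":
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data.update(changes)
        return SystemState(**data)


def default_initial_state() -> SystemState:
    """Baseline initial condition: fold-change 1 everywhere except the
    initially absent androgen-independent tumor (X2 = 0) and drugs (0)."""
    return SystemState()


# Order in which parameters enter the packed tuple consumed by :func:`rhs`.
_RHS_PARAMS = (
    "r_p1", "mu_1", "r_M", "k_CX", "delta_ICB", "k_NX", "k_RN", "k_MN",
    "r_p2", "mu_2",
    "a_VD", "a_XD", "m_D",
    "a_DC", "a_IC", "s_I", "p_C", "m_C", "k_RC", "k_MC", "mu_C",
    "rho_N", "mu_N", "k_XN", "a_IN", "s_N",
    "a_DR", "a_IR", "p_R", "m_R", "a_XR", "mu_R", "k_antiRR",
    "rho_M", "mu_M", "a_XM", "s_M", "k_antiMM",
    "a_CI", "mu_I", "k_antiI",
    "lambda_A",
    "p_D", "a_DfDr", "mu_D", "a_Df", "a_DrR",
    "lambda_V", "lambda_AI", "lambda_AR", "lambda_AM", "lambda_ICB",
)


def pack_params(params: ParameterSet) -> tuple[float, ...]:
    """Flatten a ParameterSet into the tuple layout used by :func:`rhs`."""
    return tuple(getattr(params, name) for name in _RHS_PARAMS)


def rhs(t: float, y, pt: tuple[float, ...], cx: float):
    """Time derivative of the packed state vector (1/day).

    ``pt`` is the tuple from :func:`pack_params`; ``cx`` is 1.0 while
    androgen deprivation is active, else 0.0.  This is the hot path used by
    the integrator, written with scalar arithmetic and shared sub-expressions.
    """
    (X1, X2, Dm, C2, N, R2, M, I2, A,
     Df, Dr, C1, R1, I1,
     V, anti_I, anti_R, anti_M, I_CB) = y
    (r_p1, mu_1, r_M, k_CX, delta_ICB, k_NX, k_RN, k_MN,
     r_p2, mu_2,
     a_VD, a_XD, m_D,
     a_DC, a_IC, s_I, p_C, m_C, k_RC, k_MC, mu_C,
     rho_N, mu_N, k_XN, a_IN, s_N,
     a_DR, a_IR, p_R, m_R, a_XR, mu_R, k_antiRR,
     rho_M, mu_M, a_XM, s_M, k_antiMM,
     a_CI, mu_I, k_antiI,
     lambda_A,
     p_D, a_DfDr, mu_D, a_Df, a_DrR,
     lambda_V, lambda_AI, lambda_AR, lambda_AM, lambda_ICB) = pt

    tumor = X1 + X2
    androgen_gap = 1.0 - A
    # CTL killing is potentiated linearly by the checkpoint-blockade drug;
    # NK killing is damped by Tregs and MDSCs through two negative exponentials.
    ctl_kill = k_CX * (1.0 + delta_ICB * I_CB) * C2
    nk_kill = k_NX * (math.exp(-k_RN * R2) + math.exp(-k_MN * M)) * N
    mutation = r_M * androgen_gap * X1

    dX1 = (r_p1 * A * X1 - mu_1 * androgen_gap * X1 - mutation
           - ctl_kill * X1 - nk_kill * X1)
    dX2 = (r_p2 * X2 - mu_2 * X2 + mutation
           - ctl_kill * X2 - nk_kill * X2)
    # Dendritic cells are recruited by every tumor-death flux (apoptotic
    # debris), whichever mechanism produced it.
    death_flux = (mu_1 * androgen_gap * X1 + mu_2 * X2
                  + ctl_kill * tumor + nk_kill * tumor)
    dDm = a_VD * V + a_XD * death_flux - m_D * Dm
    dC2 = (a_DC * Dm + a_IC * C2 * I2 / (s_I + I2) + p_C * m_C * C1
           - k_RC * R2 * C2 - k_MC * M * C2 - mu_C * C2)
    dN = (rho_N - mu_N * N - k_XN * N * tumor
          + a_IN * N * I2 / (s_N + I2))
    dR2 = (a_DR * Dm + a_IR * I2 + p_R * m_R * R1 + a_XR * tumor
           - mu_R * R2 - k_antiRR * anti_R * R2)
    dM = (rho_M - mu_M * M + a_XM * tumor / (s_M + tumor)
          - k_antiMM * anti_M * M)
    dI2 = a_CI * C2 - mu_I * I2 - k_antiI * anti_I * I2
    dA = lambda_A * androgen_gap - lambda_A * cx
    dDf = p_D * m_D * Dm - a_DfDr * Df
    dDr = a_DfDr * Df - mu_D * Dr
    dC1 = (a_Df * Df + a_IC * C1 * I1 / (s_I + I1)
           - m_C * C1 - k_RC * R1 * C1 - mu_C * C1)
    dR1 = (a_DrR * Dr + a_IR * I1 - m_R * R1 - mu_R * R1
           - k_antiRR * anti_R * R1)
    dI1 = a_CI * C1 - mu_I * I1 - k_antiI * anti_I * I1

    return (dX1, dX2, dDm, dC2, dN, dR2, dM, dI2, dA,
            dDf, dDr, dC1, dR1, dI1,
            -lambda_V * V, -lambda_AI * anti_I, -lambda_AR * anti_R,
            -lambda_AM * anti_M, -lambda_ICB * I_CB)


def compute_derivatives(state: SystemState, params: ParameterSet,
                        cx_active: bool = False) -> np.ndarray:
    """Validated right-hand-side evaluation at one state (1/day).

    Rejects negative or non-finite state components; inside an integration
    the raw :func:`rhs` is used instead so the solver may probe freely.
    """
    y = state.to_array()
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains non-finite components")
    if np.any(y < 0):
        bad = [STATE_NAMES[i] for i in np.where(y < 0)[0]]
        raise ValueError(f"state components must be >= 0: {', '.join(bad)}")
    return np.array(rhs(0.0, y, pack_params(params),
                        1.0 if cx_active else 0.0))
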