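"""Model parameters: named rate constants, half-lives and derived quantities.

All rates are per day and all state variables are dimensionless fold-changes,
so every parameter here is either a first-order rate (1/day), a dimensionless
saturation constant / probability, or a dimensionless effect magnitude.

Three parameters are not free but derived:

* ``lambda_*`` decay rates follow from half-lives as ``ln(2)/t_half``.
* ``mu_N``, the NK-cell turnover rate, follows the allometric law
  ``K / m**(1/4)`` with ``K = 0.0371`` and ``m`` the body mass in kg
  (0.029 kg for an average adult laboratory mouse gives 0.09/day).
* ``rho_N``, the NK source, is fixed by requiring a tumor-free steady state
  of the NK equation at baseline IL-2: ``rho_N = mu_N - a_IN/(s_N + 1)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "ParameterSet",
    "load_parameters",
    "default_parameters",
    "decay_rate_from_half_life",
    "nk_death_rate",
    "derive_nk_source",
    "ESTIMATED_PARAMETERS",
    "PARAMETER_ALIASES",
]

#: Alternate symbol spellings accepted in parameter files, mapped to the
#: canonical names (the same physical constant appears under two names in
#: different equations of the source model).
PARAMETER_ALIASES = {
    "k_NT": "k_NX",
    "k_antiIl": "k_antiI",
}

#: The 28 parameters exposed to numerical estimation by default.  The
#: remaining constants (probabilities, half-life-derived decay rates, the
#: allometric NK turnover and its steady-state source, migration/saturation
#: constants taken from the literature) are treated as fixed.
ESTIMATED_PARAMETERS = (
    "r_p1", "mu_1", "r_M", "k_CX", "delta_ICB", "k_NX", "k_RN", "k_MN",
    "r_p2", "mu_2", "a_XD", "a_DC", "a_IC", "k_RC", "k_MC", "mu_C",
    "k_XN", "a_DR", "a_IR", "a_XR", "mu_R", "k_antiRR", "rho_M", "mu_M",
    "a_XM", "k_antiMM", "a_CI", "k_antiI",
)

_DEFAULT_FILE = "params_nominal_synthetic.json"


def decay_rate_from_half_life(t_half: float) -> float:
    """First-order decay rate (1/day) for an exponential half-life in days."""
    if not (t_half > 0) or not math.isfinite(t_half):
        raise ValueError(f"half-life must be positive and finite, got {t_half}")
    return math.log(2.0) / t_half


def nk_death_rate(body_mass: float, k: float = 0.0371) -> float:
    """NK-cell turnover rate (1/day) from the allometric law ``k / m**(1/4)``.

    ``body_mass`` is in kilograms; the quarter-power scaling means a 16-fold
    heavier organism turns its NK pool over half as fast.
    """
    if not (body_mass > 0) or not math.isfinite(body_mass):
        raise ValueError(f"body mass must be positive and finite, got {body_mass}")
    return k / body_mass ** 0.25


def derive_nk_source(mu_N: float, a_IN: float, s_N: float,
                     baseline_il2: float = 1.0) -> float:
    """NK source rate enforcing a tumor-free steady state at N = 1.

    Setting dN/dt = 0 with no tumor and IL-2 at its baseline fold-change
    gives ``rho_N = mu_N - a_IN * I2 / (s_N + I2)``.  Because the IL-2
    stimulation is weak compared with turnover, rho_N is close to mu_N.
    """
    rho = mu_N - a_IN * baseline_il2 / (s_N + baseline_il2)
    if rho <= 0:
        raise ValueError(
            "inconsistent NK parameters: steady-state source rho_N = "
            f"{rho:.4g} <= 0 (IL-2 stimulation exceeds turnover)")
    return rho


# Rates, probabilities and magnitudes read directly from a parameter file.
_PRIMARY_FIELDS = (
    # androgen-dependent tumor (prostate)
    "r_p1", "mu_1", "r_M", "k_CX", "delta_ICB", "k_NX", "k_RN", "k_MN",
    # androgen-independent tumor
    "r_p2", "mu_2",
    # mature dendritic cells (prostate)
    "a_VD", "a_XD", "m_D",
    # CTL (prostate)
    "a_DC", "a_IC", "s_I", "p_C", "m_C", "k_RC", "k_MC", "mu_C",
    # NK
    "k_XN", "a_IN", "s_N",
    # Treg (prostate)
    "a_DR", "a_IR", "p_R", "m_R", "a_XR", "mu_R", "k_antiRR",
    # MDSC
    "rho_M", "mu_M", "a_XM", "s_M", "k_antiMM",
    # IL-2 (both compartments)
    "a_CI", "mu_I", "k_antiI",
    # lymphoid dendritic cells
    "p_D", "a_DfDr", "mu_D",
    # lymphoid CTL / Treg activation
    "a_Df", "a_DrR",
)

_HALF_LIFE_FIELDS = (
    "t_half_A", "t_half_V", "t_half_AI", "t_half_AR", "t_half_AM", "t_half_ICB",
)

_LAMBDA_OF_HALF_LIFE = {
    "t_half_A": "lambda_A",
    "t_half_V": "lambda_V",
    "t_half_AI": "lambda_AI",
    "t_half_AR": "lambda_AR",
    "t_half_AM": "lambda_AM",
    "t_half_ICB": "lambda_ICB",
}

_PROBABILITY_FIELDS = ("p_C", "p_R", "p_D")


@dataclass(frozen=True)
class ParameterSet:
    """All rate constants of the tumor--immune model, validated.

    Construct with :func:`load_parameters`/:func:`default_parameters`, or
    :meth:`from_dict`; use :meth:`replace` for perturbed copies.
    """

    # -- primary constants (see _PRIMARY_FIELDS for grouping) --------------
    r_p1: float
    mu_1: float
    r_M: float
    k_CX: float
    delta_ICB: float
    k_NX: float
    k_RN: float
    k_MN: float
    r_p2: float
    mu_2: float
    a_VD: float
    a_XD: float
    m_D: float
    a_DC: float
    a_IC: float
    s_I: float
    p_C: float
    m_C: float
    k_RC: float
    k_MC: float
    mu_C: float
    k_XN: float
    a_IN: float
    s_N: float
    a_DR: float
    a_IR: float
    p_R: float
    m_R: float
    a_XR: float
    mu_R: float
    k_antiRR: float
    rho_M: float
    mu_M: float
    a_XM: float
    s_M: float
    k_antiMM: float
    a_CI: float
    mu_I: float
    k_antiI: float
    p_D: float
    a_DfDr: float
    mu_D: float
    a_Df: float
    a_DrR: float
    # -- half-lives (days) and derived decay rates (1/day) -----------------
    t_half_A: float
    t_half_V: float
    t_half_AI: float
    t_half_AR: float
    t_half_AM: float
    t_half_ICB: float
    lambda_A: float
    lambda_V: float
    lambda_AI: float
    lambda_AR: float
    lambda_AM: float
    lambda_ICB: float
    # -- NK allometry and derived turnover/source ---------------------------
    K_nk: float
    m_mice: float
    mu_N: float
    rho_N: float
    # -- treatment / in-vitro auxiliary constants ---------------------------
    nk_injection_multiplier: float
    invitro_tumor_0: float
    invitro_nk_0: float
    invitro_ctl_0: float
    invitro_mdsc_0: float

    def __post_init__(self) -> None:
        for name in _PRIMARY_FIELDS + _HALF_LIFE_FIELDS + (
                "lambda_A", "lambda_V", "lambda_AI", "lambda_AR", "lambda_AM",
                "lambda_ICB", "K_nk", "m_mice", "mu_N", "rho_N",
                "nk_injection_multiplier"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, "
                                 f"got {value}")
        for name in _HALF_LIFE_FIELDS + ("mu_N", "rho_N", "m_mice", "K_nk"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        for name in _PROBABILITY_FIELDS:
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"probability {name} must lie in [0, 1], "
                                 f"got {value}")
        for t_name, l_name in _LAMBDA_OF_HALF_LIFE.items():
            expected = math.log(2.0) / getattr(self, t_name)
            actual = getattr(self, l_name)
            if abs(actual - expected) > 1e-6 * expected:
                warnings.warn(
                    f"{l_name} = {actual:.6g} is inconsistent with "
                    f"{t_name} = {getattr(self, t_name):.6g} "
                    f"(ln(2)/t_half = {expected:.6g})", stacklevel=2)

    # ------------------------------------------------------------------ API
    @classmethod
    def from_dict(cls, raw: Mapping[str, float]) -> "ParameterSet":
        """Build a validated set from a flat name -> value mapping.

        Aliases are renamed (with a warning), decay rates are derived from
        half-lives when absent, and the NK turnover/source are filled from
        the allometric and steady-state formulas when absent.
        """
        data = {k: v for k, v in raw.items() if not k.startswith("_")}
        for alias, canonical in PARAMETER_ALIASES.items():
            if alias in data:
                warnings.warn(f"parameter alias {alias!r} mapped to "
                              f"{canonical!r}", stacklevel=2)
                data.setdefault(canonical, data.pop(alias))
        missing = [n for n in _PRIMARY_FIELDS + _HALF_LIFE_FIELDS
                   if n not in data]
        if missing:
            raise KeyError(f"missing required parameters: {', '.join(missing)}")
        for t_name, l_name in _LAMBDA_OF_HALF_LIFE.items():
            data.setdefault(l_name, decay_rate_from_half_life(data[t_name]))
        data.setdefault("K_nk", 0.0371)
        data.setdefault("m_mice", 0.029)
        data.setdefault("mu_N", nk_death_rate(data["m_mice"], data["K_nk"]))
        data.setdefault("rho_N", derive_nk_source(
            data["mu_N"], data["a_IN"], data["s_N"]))
        data.setdefault("nk_injection_multiplier", 9.0)
        for name in ("invitro_tumor_0", "invitro_nk_0", "invitro_ctl_0",
                     "invitro_mdsc_0"):
            data.setdefault(name, 1.0)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown parameters: {', '.join(sorted(unknown))}")
        return cls(**data)

    def replace(self, **changes: float) -> "ParameterSet":
        """Copy with selected constants changed; derived values follow.

        Changing a half-life refreshes the matching decay rate, and changing
        the NK stimulation constants refreshes ``rho_N`` unless those derived
        values are themselves overridden explicitly.
        """
        data = self.as_dict()
        derived_targets = set()
        for t_name, l_name in _LAMBDA_OF_HALF_LIFE.items():
            if t_name in changes and l_name not in changes:
                derived_targets.add(l_name)
        if ({"mu_N", "a_IN", "s_N"} & set(changes)) and "rho_N" not in changes:
            derived_targets.add("rho_N")
        if ({"K_nk", "m_mice"} & set(changes)) and "mu_N" not in changes:
            derived_targets.add("mu_N")
            derived_targets.add("rho_N")
        data.update(changes)
        for t_name, l_name in _LAMBDA_OF_HALF_LIFE.items():
            if l_name in derived_targets:
                data[l_name] = decay_rate_from_half_life(data[t_name])
        if "mu_N" in derived_targets:
            data["mu_N"] = nk_death_rate(data["m_mice"], data["K_nk"])
        if "rho_N" in derived_targets:
            data["rho_N"] = derive_nk_source(
                data["mu_N"], data["a_IN"], data["s_N"])
        return ParameterSet(**data)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def get(self, name: str) -> float:
        return getattr(self, name)


def _parse_text(text: str, suffix: str) -> dict:
    if suffix in {".yaml", ".yml"}:
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a parameter file (flat JSON or YAML mapping of symbol -> value)."""
    path = Path(path)
    raw = _parse_text(path.read_text(), path.suffix.lower())
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: expected a flat mapping of parameter names "
                         "to values")
    return ParameterSet.from_dict(raw)


def default_parameters() -> ParameterSet:
    """The packaged nominal parameter set (synthetic stand-in values)."""
    text = (resources.files("pcaqsp") / "data" / _DEFAULT_FILE).read_text()
    return ParameterSet.from_dict(json.loads(text))


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params.as_dict(), indent=1, sort_keys=True))


def default_bounds(params: ParameterSet,
                   names: Iterable[str] = ESTIMATED_PARAMETERS,
                   lower_factor: float = 0.1,
                   upper_factor: float = 10.0) -> dict[str, tuple[float, float]]:
    """Multiplicative box bounds around the current values for estimation."""
    bounds = {}
    for name in names:
        value = params.get(name)
        if value == 0.0:
            raise ValueError(f"cannot form multiplicative bounds for {name}=0")
        bounds[name] = (lower_factor * value, upper_factor * value)
    return bounds
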