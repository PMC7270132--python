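"""Parameter estimation: objective function, synthetic data and a GA driver.

The objective is a sum of three parts mirroring the three kinds of
calibration data:

* ``Opt1`` — triple-nested mean of absolute residuals between simulated and
  observed fold-changes (per scenario, per variable, per time point) across
  the seven in-vivo combination-therapy scenarios.
* ``Opt2`` — weighted squared deviations of the two in-vitro co-culture
  ratios from their experimental anchors (tumor+/-NK after 2 days vs 0.5;
  CTL+/-MDSC after 5 days vs 0.42).
* ``Opt3`` — weighted squared deviations of week-7 tumor and MDSC ratios
  (each immunotherapy arm vs the castration-only arm) from their observed
  targets, under the ADT-then-immunotherapy protocol.

Minimisation uses a real-coded genetic algorithm (tournament selection,
blend crossover, decaying gaussian mutation, elitism) because that is the
search strategy the model was designed around; the defaults are a
population of 200, crossover fraction 0.9 and objective tolerance 1e-2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .parameters import ESTIMATED_PARAMETERS, ParameterSet, default_bounds
from .simulate import simulate, simulate_invitro_mdsc, simulate_invitro_nk
from .treatments import adt_then_immunotherapy_protocol, calibration_protocol

__all__ = [
    "Observation", "ScenarioSeries", "CalibrationDataset", "GAConfig",
    "CalibrationResult", "extrapolate_baseline", "objective_opt1",
    "objective_opt2", "objective_opt3", "objective_total", "calibrate",
    "generate_synthetic_dataset", "minimize_ga",
    "CALIBRATION_SCENARIOS", "OBSERVED_VARIABLES", "OBSERVATION_DAYS",
    "LU_CONDITIONS",
]

#: The seven in-vivo fold-change scenarios fitted by Opt1 (therapy combos
#: administered from day 0 of the observation window).
CALIBRATION_SCENARIOS = (
    (), ("CX",), ("V",), ("AI",), ("AR",), ("CX", "V"), ("AI", "AR"),
)
#: Observed series: tumor plus CTL and Treg in both compartments.
OBSERVED_VARIABLES = ("total_tumor", "C2", "R2", "C1", "R1")
#: Sampling cadence: every 2.5 weeks for 5 weeks.
OBSERVATION_DAYS = (0.0, 17.5, 35.0)
#: The three week-7 immunotherapy arms compared against castration alone.
LU_CONDITIONS = (("ICB",), ("AM",), ("ICB", "AM"))

# Calibration runs thousands of simulations; a slightly relaxed solver
# tolerance is ample for residuals compared at the 1e-2 level.
_CAL_RTOL = 1e-6
_CAL_ATOL = 1e-8


@dataclass(frozen=True)
class Observation:
    variable: str
    time: float
    value: float


@dataclass(frozen=True)
class ScenarioSeries:
    combo: tuple[str, ...]
    observations: tuple[Observation, ...]


@dataclass(frozen=True)
class CalibrationDataset:
    """Observed fold-change series plus scalar ratio targets and weights."""

    scenarios: tuple[ScenarioSeries, ...]
    nk_ratio_target: float = 0.5
    mdsc_ratio_target: float = 0.42
    nk_duration: float = 2.0
    mdsc_duration: float = 5.0
    #: per Lu condition: (tumor ratio target, MDSC ratio target) vs ADT-only
    treatment_ratio_targets: tuple[tuple[float, float], ...] = ()
    w1: float = 1.0
    w2: float = 1.0
    w_hat: tuple[float, ...] = (1.0, 1.0, 1.0)
    w_tilde: tuple[float, ...] = (1.0, 1.0, 1.0)
    horizon: float = 35.0

    def __post_init__(self) -> None:
        if self.treatment_ratio_targets and \
                len(self.treatment_ratio_targets) != len(LU_CONDITIONS):
            raise ValueError("treatment_ratio_targets must give one "
                             "(tumor, MDSC) pair per immunotherapy condition")
        for ws in (self.w_hat, self.w_tilde):
            if any(w < 0 for w in ws):
                raise ValueError("weights must be >= 0")
        for s in self.scenarios:
            for o in s.observations:
                if not 0 <= o.time <= self.horizon:
                    raise ValueError(
                        f"observation time {o.time} outside [0, {self.horizon}]")


def extrapolate_baseline(observations: Sequence[tuple[float, float]],
                         numerator_week: float = 16.0,
                         denominator_week: float = 14.0) -> float:
    """Ratio of cell counts at two ages from a least-squares line.

    Infiltrating-cell counts observed at a few ages (weeks) are fitted by
    ordinary least squares; the returned ratio of the line at week 16 over
    week 14 converts the absolute counts to the fold-change scale whose
    baseline is the 14-week-old (treatment-start) animal.
    """
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] != 2:
        raise ValueError("need at least two (week, count) observations")
    weeks, counts = obs[:, 0], obs[:, 1]
    if np.ptp(weeks) == 0:
        raise ValueError("degenerate design: all observations at one week")
    slope, intercept = np.polyfit(weeks, counts, 1)
    denom = slope * denominator_week + intercept
    if denom == 0:
        raise ZeroDivisionError("fitted line is zero at the baseline week")
    return (slope * numerator_week + intercept) / denom


def _simulate_scenario(params: ParameterSet, combo: Iterable[str],
                       horizon: float):
    return simulate(params, calibration_protocol(combo, horizon=horizon),
                    rtol=_CAL_RTOL, atol=_CAL_ATOL)


def objective_opt1(params: ParameterSet, dataset: CalibrationDataset) -> float:
    """Mean over scenarios of mean over variables of mean absolute residual."""
    if len(dataset.scenarios) != len(CALIBRATION_SCENARIOS):
        raise ValueError(f"expected {len(CALIBRATION_SCENARIOS)} scenarios, "
                         f"got {len(dataset.scenarios)}")
    scenario_means = []
    for scenario in dataset.scenarios:
        traj = _simulate_scenario(params, scenario.combo, dataset.horizon)
        per_variable: dict[str, list[float]] = {}
        for obs in scenario.observations:
            residual = abs(traj.value(obs.variable, obs.time) - obs.value)
            per_variable.setdefault(obs.variable, []).append(residual)
        variable_means = [float(np.mean(v)) for v in per_variable.values()]
        scenario_means.append(float(np.mean(variable_means)))
    return float(np.mean(scenario_means))


def objective_opt2(params: ParameterSet, dataset: CalibrationDataset) -> float:
    """Weighted squared misfit of the two in-vitro co-culture ratios."""
    score = 0.0
    if dataset.w1:
        ratio = simulate_invitro_nk(params, dataset.nk_duration,
                                    rtol=_CAL_RTOL, atol=_CAL_ATOL)
        score += dataset.w1 * (ratio - dataset.nk_ratio_target) ** 2
    if dataset.w2:
        ratio = simulate_invitro_mdsc(params, dataset.mdsc_duration,
                                      rtol=_CAL_RTOL, atol=_CAL_ATOL)
        score += dataset.w2 * (ratio - dataset.mdsc_ratio_target) ** 2
    return score


def _lu_ratios(params: ParameterSet) -> list[tuple[float, float]]:
    """Week-7 tumor and MDSC levels of each immunotherapy arm relative to
    the castration-only arm, all under the ADT-then-immunotherapy design.
    The castration-only denominators come from one shared reference run."""
    reference = simulate(params, adt_then_immunotherapy_protocol(()),
                         rtol=_CAL_RTOL, atol=_CAL_ATOL)
    t_cx = reference.value("total_tumor", 49.0)
    m_cx = reference.value("M", 49.0)
    ratios = []
    for combo in LU_CONDITIONS:
        traj = simulate(params, adt_then_immunotherapy_protocol(combo),
                        rtol=_CAL_RTOL, atol=_CAL_ATOL)
        ratios.append((traj.value("total_tumor", 49.0) / t_cx,
                       traj.value("M", 49.0) / m_cx))
    return ratios


def objective_opt3(params: ParameterSet, dataset: CalibrationDataset) -> float:
    """Weighted squared misfit of the week-7 treated/castration ratios."""
    if not dataset.treatment_ratio_targets:
        return 0.0
    score = 0.0
    for (rt, rm), (rt_bar, rm_bar), wh, wt in zip(
            _lu_ratios(params), dataset.treatment_ratio_targets,
            dataset.w_hat, dataset.w_tilde):
        score += wh * (rt - rt_bar) ** 2 + wt * (rm - rm_bar) ** 2
    return score


def objective_total(params: ParameterSet, dataset: CalibrationDataset) -> float:
    return (objective_opt1(params, dataset)
            + objective_opt2(params, dataset)
            + objective_opt3(params, dataset))


def generate_synthetic_dataset(params: ParameterSet, noise_sd: float = 0.0,
                               seed: int = 0) -> CalibrationDataset:
    """Emulated calibration data generated from known parameters.

    Simulates the seven in-vivo scenarios, samples tumor/CTL/Treg in both
    compartments at weeks 0, 2.5 and 5, and adds independent gaussian noise
    (sd ``noise_sd`` in fold-change units, truncated at zero).  The in-vitro
    and week-7 treatment-ratio targets are computed noiselessly from the
    same parameters, so at ``noise_sd = 0`` the generating parameters score
    an objective of zero up to integrator tolerance.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    scenarios = []
    for combo in CALIBRATION_SCENARIOS:
        traj = _simulate_scenario(params, combo, 35.0)
        observations = []
        for variable in OBSERVED_VARIABLES:
            for t in OBSERVATION_DAYS:
                value = traj.value(variable, t)
                if noise_sd:
                    value = max(0.0, value + rng.normal(0.0, noise_sd))
                observations.append(Observation(variable, t, value))
        scenarios.append(ScenarioSeries(combo, tuple(observations)))
    nk_ratio = simulate_invitro_nk(params, 2.0, rtol=_CAL_RTOL, atol=_CAL_ATOL)
    mdsc_ratio = simulate_invitro_mdsc(params, 5.0, rtol=_CAL_RTOL,
                                       atol=_CAL_ATOL)
    return CalibrationDataset(
        scenarios=tuple(scenarios),
        nk_ratio_target=nk_ratio,
        mdsc_ratio_target=mdsc_ratio,
        treatment_ratio_targets=tuple(_lu_ratios(params)),
    )


# --------------------------------------------------------------------- GA

@dataclass(frozen=True)
class GAConfig:
    population: int = 200
    crossover_fraction: float = 0.9
    tolerance: float = 1e-2
    generations: int = 100
    seed: int = 0
    stall_generations: int = 10
    elite_fraction: float = 0.05
    mutation_sigma: float = 0.15
    mutation_decay: float = 0.85

    def __post_init__(self) -> None:
        if self.population < 4 or self.generations < 1:
            raise ValueError("population must be >= 4 and generations >= 1")
        if not 0 <= self.crossover_fraction <= 1:
            raise ValueError("crossover_fraction must be in [0, 1]")


@dataclass(frozen=True)
class CalibrationResult:
    params: ParameterSet
    best_score: float
    trace: tuple[float, ...]
    free_names: tuple[str, ...]
    config: GAConfig


def minimize_ga(fun: Callable[[np.ndarray], float], lower: np.ndarray,
                upper: np.ndarray, config: GAConfig
                ) -> tuple[np.ndarray, float, list[float]]:
    """Real-coded genetic minimisation within box bounds.

    Tournament selection (k = 2), blend (BLX-0.5) crossover on a fraction
    of children, gaussian mutation whose scale shrinks geometrically each
    generation, and elitism.  Stops when the best score has improved by
    less than ``tolerance`` over the last ``stall_generations`` generations,
    or at the generation cap.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    if lower.shape != upper.shape or np.any(lower >= upper):
        raise ValueError("need lower < upper for every coordinate")
    dim = lower.size
    span = upper - lower
    pop = lower + rng.random((config.population, dim)) * span
    scores = np.array([fun(x) for x in pop])
    n_elite = max(1, int(round(config.elite_fraction * config.population)))
    trace = [float(scores.min())]
    sigma = config.mutation_sigma

    def tournament() -> np.ndarray:
        i, j = rng.integers(0, config.population, size=2)
        return pop[i] if scores[i] <= scores[j] else pop[j]

    for _ in range(config.generations):
        order = np.argsort(scores)
        elites = pop[order[:n_elite]].copy()
        elite_scores = scores[order[:n_elite]].copy()
        children = []
        n_children = config.population - n_elite
        n_cross = int(round(config.crossover_fraction * n_children))
        for _ in range(n_cross):
            a, b = tournament(), tournament()
            alpha = rng.random(dim) * 2.0 - 0.5  # BLX-0.5 blend
            children.append(np.clip(a + alpha * (b - a), lower, upper))
        for _ in range(n_children - n_cross):
            parent = tournament()
            child = parent + rng.normal(0.0, sigma * span, size=dim)
            children.append(np.clip(child, lower, upper))
        child_arr = np.array(children) if children else np.empty((0, dim))
        child_scores = np.array([fun(x) for x in child_arr])
        pop = np.vstack([elites, child_arr])
        scores = np.concatenate([elite_scores, child_scores])
        trace.append(float(scores.min()))
        sigma *= config.mutation_decay
        if (len(trace) > config.stall_generations
                and trace[-1 - config.stall_generations] - trace[-1]
                < config.tolerance):
            break
    best = int(np.argmin(scores))
    return pop[best].copy(), float(scores[best]), trace


def calibrate(dataset: CalibrationDataset,
              bounds: Optional[Mapping[str, tuple[float, float]]] = None,
              config: GAConfig = GAConfig(),
              start: Optional[ParameterSet] = None) -> CalibrationResult:
    """Estimate the free parameters by GA minimisation of the objective.

    ``bounds`` maps free parameter names to (lower, upper); parameters not
    listed stay fixed at their values in ``start`` (the packaged nominal set
    by default). Returns the best parameters and the per-generation trace.
    """
    from .parameters import default_parameters

    base = start if start is not None else default_parameters()
    if bounds is None:
        bounds = default_bounds(base, ESTIMATED_PARAMETERS)
    names = tuple(bounds)
    if not names:
        raise ValueError("nothing to optimise: no free parameters")
    lower = np.array([bounds[n][0] for n in names])
    upper = np.array([bounds[n][1] for n in names])

    def objective(x: np.ndarray) -> float:
        candidate = base.replace(**dict(zip(names, map(float, x))))
        try:
            return objective_total(candidate, dataset)
        except Exception:
            return float("inf")  # infeasible region: integrator blow-up

    best_x, best_score, trace = minimize_ga(objective, lower, upper, config)
    best_params = base.replace(**dict(zip(names, map(float, best_x))))
    return CalibrationResult(best_params, best_score, tuple(trace), names,
                             config)
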