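"""Combination screening, Bliss synergy, the decision tree and dose search.

Treatment efficacy is scored as tumor inhibition

    Ti(x) = 1 - T_x(t_eval) / T_untreated(t_eval),

total tumor compared with the untreated reference at the evaluation time
(week 4 of the uniform protocol). Synergy between a combination and its
parts is quantified by the Bliss combination index

    BCI(A, B) = [Ti(A) + Ti(B) - Ti(A) Ti(B)] / Ti(A + B),

the ratio of the no-interaction (independent-probability) expectation to
the observed combined inhibition; BCI < 1 is synergy, > 1 antagonism.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import networkx as nx

from .parameters import ParameterSet
from .simulate import Trajectory, simulate
from .treatments import THERAPIES, TreatmentSchedule, parse_combo, standard_protocol

__all__ = ["ScreenResult", "tumor_inhibition", "bliss_index", "bliss_union",
           "screen_combinations", "build_decision_tree", "minimal_dose_search"]

EVAL_TIME = 28.0


@dataclass(frozen=True)
class ScreenResult:
    """Inhibition score of one therapy combination.

    ``tumor_inhibition`` is a signed fraction (negative when the combination
    leaves a larger tumor than no treatment at all);
    ``tumor_fold_change_vs_baseline`` is T(t_eval)/T(0) - 1, the relative
    change against the pre-treatment tumor burden.
    """

    combo: tuple[str, ...]
    tumor_inhibition: float
    tumor_fold_change_vs_baseline: float
    eval_time: float


def tumor_inhibition(treated: Trajectory, untreated: Trajectory,
                     eval_time: float) -> float:
    """Fractional tumor inhibition of a treated vs an untreated trajectory."""
    return 1.0 - (treated.value("total_tumor", eval_time)
                  / untreated.value("total_tumor", eval_time))


def bliss_union(inhibitions: Iterable[float]) -> float:
    """No-interaction combined inhibition, 1 - prod(1 - Ti_i).

    For two treatments this is the familiar Ti_A + Ti_B - Ti_A Ti_B; the
    product form generalises it to any number of independent treatments.
    """
    expected = 1.0
    for ti in inhibitions:
        expected *= (1.0 - ti)
    return 1.0 - expected


def bliss_index(ti_a: float, ti_b: float, ti_combined: float) -> float:
    """Bliss combination index of treatments (or composites) A and B."""
    if ti_combined == 0:
        raise ZeroDivisionError(
            "Bliss index undefined: combined tumor inhibition is zero")
    return bliss_union((ti_a, ti_b)) / ti_combined


def screen_combinations(
        params: ParameterSet,
        max_size: int = len(THERAPIES),
        eval_time: float = EVAL_TIME,
        protocol: Callable[[Iterable[str]], TreatmentSchedule] = standard_protocol,
        untreated: Optional[Trajectory] = None) -> list[ScreenResult]:
    """Score every non-empty combination of up to ``max_size`` therapies.

    All combinations share a single untreated reference simulation. Results
    are sorted by decreasing inhibition.
    """
    if not 1 <= max_size <= len(THERAPIES):
        raise ValueError(f"max_size must be in 1..{len(THERAPIES)}")
    if untreated is None:
        untreated = simulate(params, TreatmentSchedule(horizon=eval_time))
    results = []
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(THERAPIES, size):
            traj = simulate(params, protocol(combo))
            ti = tumor_inhibition(traj, untreated, eval_time)
            fold = traj.value("total_tumor", eval_time) / traj.total_tumor[0] - 1.0
            results.append(ScreenResult(combo, ti, fold, eval_time))
    results.sort(key=lambda r: r.tumor_inhibition, reverse=True)
    return results


def _ti_lookup(screen: Sequence[ScreenResult]) -> dict[tuple[str, ...], ScreenResult]:
    return {r.combo: r for r in screen}


def build_decision_tree(screen: Sequence[ScreenResult], root: str = "CX",
                        bci_threshold: float = 1.0) -> nx.DiGraph:
    """Directed graph of synergistic step-wise therapy additions.

    Nodes are the combinations containing ``root``; an edge parent -> child
    (child = parent plus one therapy x) exists iff the Bliss index between
    the parent treated as a composite and x alone is below the threshold.
    Node attribute ``fold_change`` carries the relative tumor change vs the
    pre-treatment baseline; edges carry ``bci`` and ``added``.
    """
    lookup = _ti_lookup(screen)
    root = parse_combo(root)[0]
    singles = {t: lookup.get((t,)) for t in THERAPIES}
    if any(v is None for v in singles.values()):
        raise ValueError("screen must include all single-therapy results")
    nodes = [r for r in screen if root in r.combo]
    expected = 2 ** (len(THERAPIES) - 1)
    if len(nodes) != expected:
        raise ValueError(f"screen must include all {expected} combinations "
                         f"containing {root}; got {len(nodes)}")
    tree = nx.DiGraph()
    for result in nodes:
        tree.add_node(result.combo,
                      tumor_inhibition=result.tumor_inhibition,
                      fold_change=result.tumor_fold_change_vs_baseline)
    for result in nodes:
        parent = result.combo
        for therapy in THERAPIES:
            if therapy in parent:
                continue
            child = parse_combo(parent + (therapy,))
            child_result = lookup.get(child)
            if child_result is None or child_result.tumor_inhibition == 0:
                continue
            bci = bliss_index(result.tumor_inhibition,
                              singles[therapy].tumor_inhibition,
                              child_result.tumor_inhibition)
            if bci < bci_threshold:
                tree.add_edge(parent, child, bci=bci, added=therapy)
    # keep only nodes reachable from the root through synergistic edges
    reachable = {(root,)} | nx.descendants(tree, (root,))
    return tree.subgraph(reachable).copy()


def _bisect_smallest_dose(ti_of_dose: Callable[[float], float],
                          target_ti: float, tol: float = 1e-3) -> float:
    """Smallest dose fraction in (0, 1] whose inhibition reaches the target,
    assuming a monotone dose-response; bisection to ``tol`` in the dose."""
    ti_full = ti_of_dose(1.0)
    if ti_full < target_ti:
        raise ValueError(
            f"target inhibition {target_ti:.4g} unattainable: full dose "
            f"achieves {ti_full:.4g}")
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ti_of_dose(mid) >= target_ti:
            hi = mid
        else:
            lo = mid
    return hi


def minimal_dose_search(params: ParameterSet, combo: Iterable[str],
                        scaled_therapy: str, target_ti: float,
                        eval_time: float = EVAL_TIME,
                        tol: float = 1e-3,
                        protocol: Callable[[Iterable[str]], TreatmentSchedule]
                        = standard_protocol) -> float:
    """Smallest dose of one therapy (others at full dose) keeping the
    combination's tumor inhibition at or above ``target_ti``."""
    combo = parse_combo(combo)
    if scaled_therapy not in combo:
        raise ValueError(f"{scaled_therapy} is not part of {'+'.join(combo)}")
    untreated = simulate(params, TreatmentSchedule(horizon=eval_time))
    base = protocol(combo)

    def ti_of_dose(dose: float) -> float:
        traj = simulate(params, base.scale_therapy(scaled_therapy, dose))
        return tumor_inhibition(traj, untreated, eval_time)

    return _bisect_smallest_dose(ti_of_dose, target_ti, tol)
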