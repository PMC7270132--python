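import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcaqsp.screening import (_bisect_smallest_dose, bliss_index, bliss_union,
                              build_decision_tree, minimal_dose_search,
                              screen_combinations, tumor_inhibition)
from pcaqsp.simulate import simulate
from pcaqsp.treatments import THERAPIES, TreatmentSchedule, standard_protocol

fractions = st.floats(min_value=-0.5, max_value=0.95)


@pytest.fixture(scope="module")
def screen(params):
    """One shared full screen (all 127 combinations)."""
    return screen_combinations(params, max_size=7)


@pytest.fixture(scope="module")
def ti_lookup(screen):
    return {r.combo: r.tumor_inhibition for r in screen}


class TestTumorInhibition:
    def test_identical_trajectories_score_zero(self, params):
        traj = simulate(params, TreatmentSchedule(horizon=28.0))
        assert tumor_inhibition(traj, traj, 28.0) == 0.0

    def test_matches_direct_ratio(self, params):
        untreated = simulate(params, TreatmentSchedule(horizon=28.0))
        treated = simulate(params, standard_protocol("CX"))
        ti = tumor_inhibition(treated, untreated, 28.0)
        assert ti == pytest.approx(
            1 - treated.value("total_tumor", 28.0)
            / untreated.value("total_tumor", 28.0), rel=1e-12)
        assert 0 < ti < 1

    def test_eval_time_outside_span_rejected(self, params):
        short = simulate(params, TreatmentSchedule(horizon=10.0))
        long = simulate(params, TreatmentSchedule(horizon=28.0))
        with pytest.raises(ValueError):
            tumor_inhibition(short, long, 28.0)


class TestBlissIndex:
    @settings(derandomize=True, max_examples=100)
    @given(fractions, fractions)
    def test_boundary_identity_under_exact_independence(self, ti_a, ti_b):
        """When the combination achieves exactly the no-interaction effect,
        the index is 1 by construction."""
        ti_union = ti_a + ti_b - ti_a * ti_b
        if abs(ti_union) < 1e-9:
            return
        assert bliss_index(ti_a, ti_b, ti_union) == pytest.approx(1.0,
                                                                  rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(fractions, fractions)
    def test_symmetry_in_the_two_components(self, ti_a, ti_b):
        assert bliss_index(ti_a, ti_b, 0.5) == pytest.approx(
            bliss_index(ti_b, ti_a, 0.5), rel=1e-12)

    def test_zero_combined_effect_rejected(self):
        with pytest.raises(ZeroDivisionError):
            bliss_index(0.2, 0.3, 0.0)

    def test_union_product_form_matches_pairwise(self):
        tis = [0.2, 0.3, 0.4]
        step = bliss_union([bliss_union(tis[:2]), tis[2]])
        assert bliss_union(tis) == pytest.approx(step, rel=1e-12)


class TestScreen:
    def test_combinatorial_counts(self, params, screen):
        assert len(screen) == 127
        singles = screen_combinations(params, max_size=1)
        assert len(singles) == 7
        assert {r.combo[0] for r in singles} == set(THERAPIES)

    def test_sorted_by_inhibition(self, screen):
        tis = [r.tumor_inhibition for r in screen]
        assert tis == sorted(tis, reverse=True)

    def test_shared_reference_equals_per_combo_recomputation(self, params,
                                                             ti_lookup):
        untreated = simulate(params, TreatmentSchedule(horizon=28.0))
        for combo in [("CX",), ("ICB", "AM"), ("CX", "V", "ICB")]:
            treated = simulate(params, standard_protocol(combo))
            assert ti_lookup[combo] == pytest.approx(
                tumor_inhibition(treated, untreated, 28.0), abs=1e-12)

    def test_baseline_fold_change_consistent(self, screen):
        for result in screen:
            # inhibition and baseline change describe the same endpoint
            assert math.isfinite(result.tumor_fold_change_vs_baseline)
            assert result.eval_time == 28.0

    def test_max_size_out_of_range(self, params):
        with pytest.raises(ValueError):
            screen_combinations(params, max_size=0)


class TestDecisionTree:
    def test_threshold_zero_leaves_bare_root(self, screen):
        tree = build_decision_tree(screen, bci_threshold=0.0)
        assert set(tree.nodes) == {("CX",)}
        assert tree.number_of_edges() == 0

    def test_nodes_all_contain_root_and_edges_are_synergistic(self, screen,
                                                              ti_lookup):
        tree = build_decision_tree(screen, bci_threshold=1.0)
        for node in tree.nodes:
            assert "CX" in node
        for parent, child, data in tree.edges(data=True):
            assert set(child) == set(parent) | {data["added"]}
            assert data["bci"] < 1.0
            expected = bliss_index(ti_lookup[parent],
                                   ti_lookup[(data["added"],)],
                                   ti_lookup[child])
            assert data["bci"] == pytest.approx(expected, rel=1e-12)

    def test_nodes_carry_baseline_fold_change(self, screen):
        tree = build_decision_tree(screen)
        for _, data in tree.nodes(data=True):
            assert "fold_change" in data

    def test_incomplete_screen_rejected(self, params):
        partial = screen_combinations(params, max_size=1)
        with pytest.raises(ValueError):
            build_decision_tree(partial)


class TestMinimalDose:
    def test_bisection_on_synthetic_monotone_response(self):
        # closed-form monotone dose-response: Ti(d) = 0.8 * d
        dose = _bisect_smallest_dose(lambda d: 0.8 * d, 0.4, tol=1e-4)
        assert dose == pytest.approx(0.5, abs=2e-4)

    def test_target_at_full_dose_returns_one(self):
        dose = _bisect_smallest_dose(lambda d: 0.8 * d, 0.8, tol=1e-3)
        assert dose == pytest.approx(1.0, abs=2e-3)

    def test_zero_target_returns_smallest_probe(self):
        dose = _bisect_smallest_dose(lambda d: 0.8 * d, 0.0, tol=1e-3)
        assert dose <= 1e-3

    def test_unattainable_target_reports_full_dose_effect(self):
        with pytest.raises(ValueError, match="0.8"):
            _bisect_smallest_dose(lambda d: 0.8 * d, 0.9)

    def test_icb_dose_response_is_monotone(self, params, ti_lookup):
        """Tumor inhibition of CX+ICB is non-decreasing in the ICB dose,
        which is what makes the bisection search valid."""
        untreated = simulate(params, TreatmentSchedule(horizon=28.0))
        base = standard_protocol(("CX", "ICB"))
        tis = []
        for dose in (0.0, 0.25, 0.5, 0.75, 1.0):
            traj = simulate(params, base.scale_therapy("ICB", dose))
            tis.append(tumor_inhibition(traj, untreated, 28.0))
        assert np.all(np.diff(tis) >= -1e-9)
        # dose 0 reduces to CX alone, up to event-splitting solver error
        assert tis[0] == pytest.approx(ti_lookup[("CX",)], abs=1e-7)

    def test_search_recovers_probed_dose(self, params, ti_lookup):
        untreated = simulate(params, TreatmentSchedule(horizon=28.0))
        base = standard_protocol(("CX", "ICB"))
        half = simulate(params, base.scale_therapy("ICB", 0.5))
        target = tumor_inhibition(half, untreated, 28.0)
        dose = minimal_dose_search(params, ("CX", "ICB"), "ICB", target)
        assert dose == pytest.approx(0.5, abs=2e-3)

    def test_therapy_outside_combo_rejected(self, params):
        with pytest.raises(ValueError):
            minimal_dose_search(params, ("CX",), "ICB", 0.1)
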