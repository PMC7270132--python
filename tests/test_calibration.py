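import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcaqsp.calibration import (CALIBRATION_SCENARIOS, CalibrationDataset,
                                GAConfig, Observation, ScenarioSeries,
                                calibrate, extrapolate_baseline,
                                generate_synthetic_dataset, minimize_ga,
                                objective_opt1, objective_opt2,
                                objective_opt3, objective_total,
                                _lu_ratios, _simulate_scenario)


@pytest.fixture(scope="module")
def noiseless(params):
    return generate_synthetic_dataset(params, noise_sd=0.0, seed=42)


class TestBaselineExtrapolation:
    def test_exact_line_through_origin(self):
        obs = [(6, 12.0), (9, 18.0), (16, 32.0)]  # y = 2 * week
        assert extrapolate_baseline(obs) == pytest.approx(32.0 / 28.0,
                                                          rel=1e-12)

    def test_constant_counts_give_unit_ratio(self):
        assert extrapolate_baseline([(6, 5.0), (9, 5.0), (16, 5.0)]) \
            == pytest.approx(1.0, rel=1e-12)

    def test_noisy_points_match_normal_equations(self):
        obs = np.array([(6.0, 11.2), (9.0, 19.7), (16.0, 30.1)])
        w, c = obs[:, 0], obs[:, 1]
        # closed-form OLS: slope and intercept from the normal equations
        slope = (np.mean(w * c) - w.mean() * c.mean()) / \
            (np.mean(w * w) - w.mean() ** 2)
        intercept = c.mean() - slope * w.mean()
        expected = (slope * 16 + intercept) / (slope * 14 + intercept)
        assert extrapolate_baseline(obs) == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_invariant_to_uniform_count_scaling(self, scale):
        obs = [(6, 11.2), (9, 19.7), (16, 30.1)]
        scaled = [(w, scale * c) for w, c in obs]
        assert extrapolate_baseline(scaled) == pytest.approx(
            extrapolate_baseline(obs), rel=1e-9)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            extrapolate_baseline([(9, 1.0), (9, 2.0)])


class TestObjectiveComponents:
    def test_noiseless_truth_scores_zero(self, params, noiseless):
        assert objective_opt1(params, noiseless) == pytest.approx(0.0,
                                                                  abs=1e-6)
        assert objective_opt2(params, noiseless) == pytest.approx(0.0,
                                                                  abs=1e-10)
        assert objective_opt3(params, noiseless) == pytest.approx(0.0,
                                                                  abs=1e-10)

    def test_opt1_nested_mean_arithmetic(self, params, noiseless):
        """Shifting the observations of one scenario's single variable by
        known residuals moves Opt1 by exactly the nested-mean amount."""
        traj = _simulate_scenario(params, (), 35.0)
        obs = tuple(
            Observation("total_tumor", t,
                        traj.value("total_tumor", t) + r)
            for t, r in [(0.0, 0.1), (17.5, 0.3)])
        scenarios = [ScenarioSeries(c, tuple()) for c in
                     CALIBRATION_SCENARIOS]
        scenarios[0] = ScenarioSeries((), obs)
        # untouched scenarios contribute nothing: give them one exact point
        for i, combo in enumerate(CALIBRATION_SCENARIOS[1:], start=1):
            t_exact = _simulate_scenario(params, combo, 35.0)
            scenarios[i] = ScenarioSeries(combo, (Observation(
                "total_tumor", 35.0, t_exact.value("total_tumor", 35.0)),))
        dataset = CalibrationDataset(scenarios=tuple(scenarios))
        # inner mean |residual| = 0.2, averaged over 7 scenarios
        assert objective_opt1(params, dataset) == pytest.approx(
            0.2 / 7, abs=1e-6)

    def test_opt1_requires_all_scenarios(self, params, noiseless):
        truncated = CalibrationDataset(scenarios=noiseless.scenarios[:5])
        with pytest.raises(ValueError, match="scenarios"):
            objective_opt1(params, truncated)

    def test_opt1_rises_away_from_truth(self, params, noiseless):
        perturbed = params.replace(r_p1=params.r_p1 * 1.1)
        assert objective_opt1(perturbed, noiseless) > 1e-3

    def test_opt2_direct_arithmetic(self, params, noiseless):
        # shift one target by 0.1 with unit weight: contribution 0.01
        shifted = CalibrationDataset(
            scenarios=noiseless.scenarios,
            nk_ratio_target=noiseless.nk_ratio_target - 0.1,
            mdsc_ratio_target=noiseless.mdsc_ratio_target,
            treatment_ratio_targets=noiseless.treatment_ratio_targets)
        assert objective_opt2(params, shifted) == pytest.approx(0.01,
                                                                abs=1e-6)

    def test_opt2_zero_weights_score_zero(self, params, noiseless):
        unweighted = CalibrationDataset(
            scenarios=noiseless.scenarios, w1=0.0, w2=0.0,
            nk_ratio_target=0.9, mdsc_ratio_target=0.9,
            treatment_ratio_targets=noiseless.treatment_ratio_targets)
        assert objective_opt2(params, unweighted) == 0.0

    def test_opt3_weighted_arithmetic(self, params, noiseless):
        # first condition's tumor ratio off by 0.1 with weight 2 -> 0.02
        targets = list(noiseless.treatment_ratio_targets)
        targets[0] = (targets[0][0] - 0.1, targets[0][1])
        shifted = CalibrationDataset(
            scenarios=noiseless.scenarios,
            nk_ratio_target=noiseless.nk_ratio_target,
            mdsc_ratio_target=noiseless.mdsc_ratio_target,
            treatment_ratio_targets=tuple(targets),
            w_hat=(2.0, 1.0, 1.0))
        assert objective_opt3(params, shifted) == pytest.approx(0.02,
                                                                abs=1e-6)

    def test_lu_denominators_are_shared(self, params):
        """The castration-only reference is computed once; recomputing it
        per condition gives the same ratios."""
        from pcaqsp.simulate import simulate
        from pcaqsp.treatments import adt_then_immunotherapy_protocol

        ratios = _lu_ratios(params)
        for combo, (rt, rm) in zip((("ICB",), ("AM",), ("ICB", "AM")),
                                   ratios):
            ref = simulate(params, adt_then_immunotherapy_protocol(()),
                           rtol=1e-6, atol=1e-8)
            arm = simulate(params, adt_then_immunotherapy_protocol(combo),
                           rtol=1e-6, atol=1e-8)
            assert rt == pytest.approx(
                arm.value("total_tumor", 49.0) / ref.value("total_tumor",
                                                           49.0), rel=1e-9)
            assert rm == pytest.approx(
                arm.value("M", 49.0) / ref.value("M", 49.0), rel=1e-9)

    def test_objective_is_nonnegative(self, params, noiseless):
        assert objective_total(params, noiseless) >= 0.0
        perturbed = params.replace(r_p1=params.r_p1 * 1.3)
        assert objective_total(perturbed, noiseless) > 0.0


class TestSyntheticDataset:
    def test_same_seed_reproduces_dataset(self, params):
        a = generate_synthetic_dataset(params, noise_sd=0.05, seed=7)
        b = generate_synthetic_dataset(params, noise_sd=0.05, seed=7)
        assert a == b

    def test_different_seed_changes_noise(self, params):
        a = generate_synthetic_dataset(params, noise_sd=0.05, seed=7)
        b = generate_synthetic_dataset(params, noise_sd=0.05, seed=8)
        assert a != b

    def test_structure_matches_study_design(self, noiseless):
        assert len(noiseless.scenarios) == 7
        for scenario in noiseless.scenarios:
            times = {o.time for o in scenario.observations}
            assert times == {0.0, 17.5, 35.0}
            variables = {o.variable for o in scenario.observations}
            assert variables == {"total_tumor", "C2", "R2", "C1", "R1"}
        assert len(noiseless.treatment_ratio_targets) == 3

    def test_noise_truncated_at_zero(self, params):
        noisy = generate_synthetic_dataset(params, noise_sd=5.0, seed=1)
        values = [o.value for s in noisy.scenarios for o in s.observations]
        assert min(values) >= 0.0

    def test_opt1_at_truth_matches_folded_normal_mean(self, params):
        """With additive N(0, sd) noise the expected |residual| is
        sd * sqrt(2/pi); the nested means preserve that expectation."""
        sd = 0.05
        noisy = generate_synthetic_dataset(params, noise_sd=sd, seed=3)
        expected = sd * np.sqrt(2 / np.pi)
        # 105 observations: allow generous Monte-Carlo slack
        assert objective_opt1(params, noisy) == pytest.approx(expected,
                                                              rel=0.5)


class TestGeneticAlgorithm:
    def test_minimizes_smooth_bowl(self):
        target = np.array([0.3, -0.2, 0.7])
        best, score, trace = minimize_ga(
            lambda x: float(np.sum((x - target) ** 2)),
            lower=np.array([-1.0, -1.0, -1.0]),
            upper=np.array([1.0, 1.0, 1.0]),
            config=GAConfig(population=40, generations=60, tolerance=1e-12,
                            seed=1))
        assert score < 1e-4
        assert best == pytest.approx(target, abs=0.02)
        assert trace == sorted(trace, reverse=True)  # monotone via elitism

    def test_trace_is_deterministic_given_seed(self, params, noiseless):
        bounds = {"r_p1": (0.5 * params.r_p1, 2.0 * params.r_p1)}
        config = GAConfig(population=8, generations=2, tolerance=1e-9, seed=5)
        a = calibrate(noiseless, bounds=bounds, config=config, start=params)
        b = calibrate(noiseless, bounds=bounds, config=config, start=params)
        assert a.trace == b.trace
        assert a.params == b.params

    def test_recovers_growth_and_death_rates(self, params, noiseless):
        """Tumor proliferation and androgen-deprivation death rates are
        recovered from noiseless synthetic data at a reduced GA budget."""
        free = ("r_p1", "mu_1")
        bounds = {n: (0.5 * params.get(n), 2.0 * params.get(n))
                  for n in free}
        config = GAConfig(population=20, crossover_fraction=0.9,
                          tolerance=1e-8, generations=18, seed=11)
        result = calibrate(noiseless, bounds=bounds, config=config,
                           start=params)
        for name in free:
            assert result.params.get(name) == pytest.approx(
                params.get(name), rel=0.2), name
        assert result.best_score < 1e-2

    def test_empty_bounds_rejected(self, params, noiseless):
        with pytest.raises(ValueError, match="free parameters"):
            calibrate(noiseless, bounds={}, start=params)

    def test_invalid_box_rejected(self):
        with pytest.raises(ValueError):
            minimize_ga(lambda x: 0.0, np.array([1.0]), np.array([1.0]),
                        GAConfig(population=4, generations=1))
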