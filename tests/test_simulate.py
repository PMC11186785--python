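import numpy as np
import pytest
from scipy import stats

import stochclock as sc
from stochclock.effects import effects_from_arrays
from stochclock.simulate import (
    beta_to_quantile,
    quantile_to_beta,
    simulate_end_state_batch,
    step_quantiles,
)

HALF_NORMAL_MEAN = np.sqrt(2 / np.pi)


def single_cpg_effects(ground=0.5, old=0.9):
    return effects_from_arrays(["cg0"], [ground], [old])


class TestAlterationProbability:
    def test_zero_effect(self):
        assert sc.alteration_probability(0.0, 9.25) == 0.0

    def test_fitted_scale_value(self):
        # 1 - exp(-9.25 * 0.05) = 1 - exp(-0.4625)
        assert sc.alteration_probability(0.05, 9.25) == pytest.approx(
            0.3703, abs=5e-5
        )

    def test_saturation(self):
        assert sc.alteration_probability(0.01, 1e6) == pytest.approx(1.0)

    def test_monotone_in_both_arguments(self):
        effects = np.linspace(0, 0.5, 20)
        probs = sc.alteration_probability(effects, 5.0)
        assert np.all(np.diff(probs) > 0)
        gammas = np.linspace(0.1, 50, 20)
        probs_g = [sc.alteration_probability(0.1, g) for g in gammas]
        assert np.all(np.diff(probs_g) > 0)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            sc.alteration_probability(0.1, -1.0)


class TestSimParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"gamma": -1, "sigma": 0.1},
            {"gamma": 1, "sigma": -0.1},
            {"gamma": 1, "sigma": 0.1, "steps_per_year": 0},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            sc.SimParams(**kwargs)

    def test_step_count_anchor(self):
        params = sc.SimParams(9.25, 0.0005, steps_per_year=35, base_age=45)
        assert sc.step_count(params, 82) == 1295

    def test_step_count_fractional_age_rounds(self):
        params = sc.SimParams(1, 0.001)
        assert sc.step_count(params, 45.5) == round(35 * 0.5)

    def test_age_below_base_rejected(self):
        params = sc.SimParams(1, 0.001)
        with pytest.raises(ValueError):
            sc.step_count(params, 40)


class TestStepAndSample:
    def test_sigma_zero_is_identity(self):
        effects = single_cpg_effects()
        params = sc.SimParams(9.25, 0.0)
        rng = np.random.default_rng(0)
        out = sc.simulate_sample(np.array([0.5]), effects, params, 60, rng)
        assert out[0] == pytest.approx(0.5, abs=1e-12)

    def test_gamma_zero_is_identity(self):
        effects = single_cpg_effects()
        params = sc.SimParams(0.0, 0.01)
        rng = np.random.default_rng(0)
        out = sc.simulate_sample(np.array([0.5]), effects, params, 60, rng)
        assert out[0] == pytest.approx(0.5, abs=1e-12)

    def test_zero_steps_round_trip(self):
        effects = single_cpg_effects(0.37, 0.8)
        params = sc.SimParams(9.25, 0.0005)
        rng = np.random.default_rng(0)
        out = sc.simulate_sample(np.array([0.37]), effects, params, 45, rng)
        assert abs(out[0] - 0.37) < 1e-9

    def test_trajectory_step_bookkeeping(self):
        effects = single_cpg_effects()
        params = sc.SimParams(9.25, 0.0005)
        traj = sc.simulate_trajectory(
            np.array([0.5]), effects, params, 47, np.random.default_rng(0)
        )
        assert traj.shape == (2 * 35 + 1, 1)

    def test_half_normal_drift_monte_carlo(self):
        # p_c ~= 1, 1000 steps: expected quantile drift is
        # 1000 * sigma * sqrt(2/pi) ~= 0.399
        sigma = 0.0005
        effects = single_cpg_effects(0.5, 1.0)
        params = sc.SimParams(1e6, sigma)  # saturated alteration prob
        rng = np.random.default_rng(7)
        end = simulate_end_state_batch(
            np.array([0.5]), effects, params, 1000, 1000, rng
        )
        drift = beta_to_quantile(end[:, 0]) - 0.0
        expected = 1000 * sigma * HALF_NORMAL_MEAN
        se = np.std(drift, ddof=1) / np.sqrt(len(drift))
        assert abs(np.mean(drift) - expected) < 3 * se

    def test_expected_drift_formula_with_partial_alteration(self):
        # E[drift after T steps] = T * p_c * sigma * sqrt(2/pi)
        ground, old, gamma, sigma, T = 0.4, 0.5, 9.25, 0.002, 400
        effects = single_cpg_effects(ground, old)
        p_c = sc.alteration_probability(old - ground, gamma)
        params = sc.SimParams(gamma, sigma)
        rng = np.random.default_rng(11)
        end = simulate_end_state_batch(
            np.array([ground]), effects, params, T, 2000, rng
        )
        drift = beta_to_quantile(end[:, 0]) - beta_to_quantile(
            np.array([ground])
        )
        expected = T * p_c * sigma * HALF_NORMAL_MEAN
        se = np.std(drift, ddof=1) / np.sqrt(len(drift))
        assert abs(np.mean(drift) - expected) < 3 * se

    def test_negative_effect_drifts_down(self):
        effects = single_cpg_effects(0.6, 0.3)
        params = sc.SimParams(9.25, 0.0005)
        rng = np.random.default_rng(3)
        end = simulate_end_state_batch(
            np.array([0.6]), effects, params, 1295, 500, rng
        )
        assert end[:, 0].mean() < 0.6

    def test_betas_stay_strictly_inside_unit_interval(self):
        effects = effects_from_arrays(
            ["cg0", "cg1"], [0.001, 0.999], [0.2, 0.8]
        )
        params = sc.SimParams(50, 0.05)
        rng = np.random.default_rng(1)
        out = sc.simulate_sample(
            np.array([0.001, 0.999]), effects, params, 83, rng
        )
        assert np.all(out > 0) and np.all(out < 1)


class TestHeteroscedasticity:
    def test_delta_beta_maximal_at_half(self):
        # same quantile drift applied at betas 0.05, 0.5, 0.95
        sigma, T = 0.001, 200
        ids = ["cg0", "cg1", "cg2"]
        starts = np.array([0.05, 0.5, 0.95])
        effects = effects_from_arrays(ids, starts, np.minimum(starts + 0.1, 1))
        params = sc.SimParams(1e6, sigma)
        rng = np.random.default_rng(5)
        end = simulate_end_state_batch(starts, effects, params, T, 500, rng)
        mean_abs_change = np.abs(end - starts).mean(axis=0)
        assert mean_abs_change[1] > mean_abs_change[0]
        assert mean_abs_change[1] > mean_abs_change[2]


class TestLinearRegime:
    def test_mean_beta_drift_linear_in_time(self):
        # a CpG starting at 0.3 with small sigma drifts ~linearly
        effects = single_cpg_effects(0.3, 0.7)
        params = sc.SimParams(1e6, 0.0005)
        paths = []
        for seed in range(100):
            paths.append(
                sc.simulate_trajectory(
                    np.array([0.3]), effects, params,
                    params.base_age + 300 / 35,
                    np.random.default_rng(seed),
                )[:, 0]
            )
        mean_path = np.mean(paths, axis=0)
        t = np.arange(mean_path.size)
        fit = stats.linregress(t, mean_path)
        assert fit.rvalue**2 > 0.99


def test_quantile_transform_round_trip():
    betas = np.array([1e-6, 0.01, 0.5, 0.99, 1 - 1e-6])
    assert np.allclose(
        quantile_to_beta(beta_to_quantile(betas)), betas, atol=1e-12
    )


def test_step_quantiles_broadcasts_2d():
    x = np.zeros((4, 3))
    out = step_quantiles(
        x, np.array([1.0, 1.0, 0.0]), np.array([1.0, -1.0, 1.0]), 0.1,
        np.random.default_rng(0),
    )
    assert np.all(out[:, 0] > 0)
    assert np.all(out[:, 1] < 0)
    assert np.all(out[:, 2] == 0)
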