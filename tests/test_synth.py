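import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stochclock as sc
from stochclock.synth import make_cell_fractions


class TestMakeReferencePanel:
    def test_betas_in_unit_interval(self, panel):
        for mat in (panel.young, panel.old):
            vals = mat.to_numpy()
            assert np.all(vals >= 0) and np.all(vals <= 1)

    def test_shared_cpg_sets(self, panel):
        assert panel.young.index.equals(panel.old.index)
        assert panel.young.index.equals(panel.true_effects.index)

    def test_effect_magnitude_cap(self):
        p = sc.make_reference_panel(200, 10, 10, effect_sd=0.05,
                                    max_abs_effect=0.05, seed=0)
        assert p.true_effects["effect_size"].abs().max() <= 0.05 + 1e-12

    def test_zero_effect_sd_groups_match(self):
        p = sc.make_reference_panel(300, 200, 200, effect_sd=0.0, seed=1)
        diff = p.old.mean(axis=1) - p.young.mean(axis=1)
        # zero true effect: observed group difference is pure noise
        assert np.abs(diff).mean() < 0.01
        assert np.all(p.true_effects["effect_size"] == 0)

    def test_forced_hypermethylation_sign(self):
        p = sc.make_reference_panel(150, 5, 5, frac_hyper=1.0, seed=2)
        nonzero = p.true_effects["effect_size"]
        assert np.all(nonzero[nonzero != 0] > 0)

    def test_empirical_effects_track_truth(self):
        p = sc.make_reference_panel(353, 50, 50, seed=4)
        emp = p.old.mean(axis=1) - p.young.mean(axis=1)
        r = np.corrcoef(emp, p.true_effects["effect_size"])[0, 1]
        assert r > 0.9

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_cpgs": 1, "n_young": 5, "n_old": 5},
            {"n_cpgs": 10, "n_young": 1, "n_old": 5},
            {"n_cpgs": 10, "n_young": 5, "n_old": 5, "effect_sd": -0.1},
        ],
    )
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            sc.make_reference_panel(**kwargs)

    def test_excessive_censoring_rejected(self):
        with pytest.raises(ValueError, match="censor"):
            sc.make_reference_panel(
                500, 5, 5, effect_sd=0.5, max_abs_effect=0.9, seed=0
            )


class TestMakeCellFractions:
    def test_rows_exactly_stochastic(self):
        frac = make_cell_fractions(50, 12, noise=0.05, seed=0)
        sums = frac.to_numpy().sum(axis=1)
        assert np.all(np.abs(sums - 1.0) < 1e-12)
        assert np.all(frac.to_numpy() >= 0)

    def test_no_deltas_rows_match_base(self):
        base = np.array([0.4, 0.3, 0.2, 0.1])
        frac = make_cell_fractions(500, 4, base=base, noise=0.02, seed=1)
        assert np.allclose(frac.mean(axis=0), base, atol=0.01)

    def test_forced_group_shift(self):
        labels = np.array(["A"] * 100 + ["B"] * 100)
        frac = make_cell_fractions(
            200, 2, base=np.array([0.5, 0.5]),
            group_deltas={"A": np.array([0.1, -0.1])},
            group_labels=labels, noise=0.01, seed=2,
        )
        mean_a = frac.iloc[:100, 0].mean()
        assert mean_a == pytest.approx(0.6, abs=0.01)

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            make_cell_fractions(5, 3, base=np.array([0.5, 0.5, 0.5]))


class TestMakeAgingCohort:
    def test_null_dynamics_returns_drawn_profiles(self, panel):
        params = sc.SimParams(9.25, 0.0, base_age=45)
        spec = sc.AgingCohortSpec(
            n_samples=5, age_range=(45, 80), params=params, seed=3
        )
        betas, meta = sc.make_aging_cohort(panel, spec)
        pool = panel.young.loc[betas.index].to_numpy()
        for col in betas.columns:
            sample = betas[col].to_numpy()
            dists = np.abs(pool - sample[:, None]).max(axis=0)
            assert dists.min() < 1e-8  # matches some young profile exactly

    def test_age_below_base_rejected(self, panel):
        params = sc.SimParams(9.25, 0.0005, base_age=45)
        spec = sc.AgingCohortSpec(
            n_samples=5, age_range=(30, 80), params=params, seed=0
        )
        with pytest.raises(ValueError, match="base age"):
            sc.make_aging_cohort(panel, spec)

    def test_betas_in_unit_interval(self, panel, paper_params):
        spec = sc.AgingCohortSpec(
            n_samples=10, age_range=(45, 83), params=paper_params, seed=4
        )
        betas, _ = sc.make_aging_cohort(panel, spec)
        vals = betas.to_numpy()
        assert np.all(vals > 0) and np.all(vals < 1)

    def test_beta_space_covariate_offset_group_difference(
        self, panel, paper_params
    ):
        n = 200
        rng = np.random.default_rng(5)
        male = rng.integers(0, 2, n).astype(float)
        offsets = np.zeros(len(panel.true_effects))
        offsets[:50] = 0.02
        eff = sc.NonstochasticEffect(
            "male", offsets, male, space="beta"
        )
        spec = sc.AgingCohortSpec(
            n_samples=n, age_range=(45, 50), params=paper_params,
            nonstochastic_effects=[eff], seed=6,
        )
        betas, meta = sc.make_aging_cohort(panel, spec)
        group_diff = (
            betas.loc[:, male == 1].to_numpy()[:50].mean()
            - betas.loc[:, male == 0].to_numpy()[:50].mean()
        )
        assert group_diff == pytest.approx(0.02, abs=0.005)

    def test_zero_cell_deltas_leave_fractions_equal(self, panel, paper_params):
        labels = np.array(["A", "B"] * 10)
        shift = sc.CellShift(
            group_labels=labels, deltas={}, k=4, fraction_noise=0.0
        )
        spec = sc.AgingCohortSpec(
            n_samples=20, age_range=(45, 60), params=paper_params,
            cell_shift=shift, seed=7,
        )
        _, meta = sc.make_aging_cohort(panel, spec)
        frac = meta[[c for c in meta.columns if c.startswith("frac_")]]
        assert np.allclose(frac.to_numpy(), 0.25)

    def test_metadata_fraction_rows_sum_to_one(self, panel, paper_params):
        labels = np.array(["A"] * 10 + ["B"] * 10)
        shift = sc.CellShift(
            group_labels=labels,
            deltas={"A": np.r_[0.05, -0.05, np.zeros(10)]},
            fraction_noise=0.01,
        )
        spec = sc.AgingCohortSpec(
            n_samples=20, age_range=(45, 60), params=paper_params,
            cell_shift=shift, seed=8,
        )
        _, meta = sc.make_aging_cohort(panel, spec)
        frac = meta[[c for c in meta.columns if c.startswith("frac_")]]
        assert np.allclose(frac.sum(axis=1), 1.0, atol=1e-12)

    def test_age_slope_signs_recover_true_effect_signs(
        self, panel, paper_params
    ):
        spec = sc.AgingCohortSpec(
            n_samples=150, age_range=(45, 83), params=paper_params, seed=9
        )
        betas, meta = sc.make_aging_cohort(panel, spec)
        ages = meta["age"].to_numpy(dtype=float)
        true_eff = panel.true_effects["effect_size"].to_numpy()
        # restrict to CpGs with effects above the noise floor
        strong = np.abs(true_eff) > 0.01
        agree = []
        for i in np.flatnonzero(strong):
            slope = stats.linregress(ages, betas.iloc[i].to_numpy()).slope
            agree.append(np.sign(slope) == np.sign(true_eff[i]))
        assert np.mean(agree) >= 0.95

    def test_explicit_ages_respected(self, panel, paper_params):
        ages = np.array([50.0, 60.0, 70.0])
        spec = sc.AgingCohortSpec(
            n_samples=3, age_range=(45, 83), params=paper_params, seed=10,
            ages=ages,
        )
        _, meta = sc.make_aging_cohort(panel, spec)
        assert np.array_equal(meta["age"].to_numpy(), ages)
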