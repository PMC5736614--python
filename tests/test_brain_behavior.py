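import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from feedlearn.brain_behavior import (
    SampleSizeError,
    ceiling_filter,
    hierarchical_test,
    lagged_prediction,
    mc_adjust,
    mean_pairwise_correlation,
    residualize,
    run_hierarchical_battery,
)
from feedlearn.synthetic_cohort import CohortConfig, TrajectoryCoef, generate_cohort
from feedlearn.trajectory_models import fit_ladder_by, fit_mixed


def coupled_cohort(coupling=0.5, n_subjects=250, seed=0, inter_roi_corr=0.0, **kw):
    defaults = dict(
        activity_coef=TrajectoryCoef(b0=2.0, b1=0.25, b2=-0.05),
        performance_coef=TrajectoryCoef(b0=80.0, b1=0.16, b2=-0.04),
    )
    defaults.update(kw)
    cfg = CohortConfig(
        n_subjects=n_subjects,
        rois=("dorsal_caudate",),
        contrasts=("informative_value",),
        coupling={("dorsal_caudate", "informative_value"): coupling},
        ceiling_rate=0.0,
        inter_roi_corr=inter_roi_corr,
        **defaults,
    )
    df, truth = generate_cohort(cfg, seed=seed)
    return df, cfg


class TestResidualize:
    def test_on_curve_gives_zero_residual(self):
        df, cfg = coupled_cohort(n_subjects=60, seed=1)
        fits = fit_ladder_by(df, "activity")
        key = ("dorsal_caudate", "informative_value")
        fit = fits[key].selected
        synthetic = df.head(20).copy()
        synthetic["activity"] = fit.fixed_prediction(synthetic["age"].to_numpy())
        out = residualize(synthetic, {key: fits[key]})
        assert np.allclose(out["activity_residual"], 0.0, atol=1e-10)

    def test_residual_mean_near_zero_on_fitting_sample(self):
        """Least-squares property: with a balanced design (equal per-subject
        weights) the fitting-sample residuals average to exactly zero; under
        dropout the same holds in the GLS-weighted sense."""
        df, cfg = coupled_cohort(n_subjects=150, seed=2, retention_per_wave=1.0)
        fits = fit_ladder_by(df, "activity")
        out = residualize(df, fits)
        rel = abs(out["activity_residual"].mean()) / out["activity_residual"].std()
        assert rel < 1e-6

    def test_missing_stratum_skipped_with_warning(self):
        df, cfg = coupled_cohort(n_subjects=40, seed=3)
        with pytest.warns(UserWarning):
            out = residualize(df, {})
        assert out.empty

    def test_known_coupling_recovered_in_correlation(self):
        df, cfg = coupled_cohort(coupling=0.5, n_subjects=1000, seed=4)
        fits = fit_ladder_by(df, "activity")
        out = residualize(df, fits)
        r = np.corrcoef(out["activity_residual"], out["performance"])[0, 1]
        # generating partial correlation: 0.5*sd_resid / sqrt((0.5*sd_resid)^2 + sd_perf^2)
        sd_resid = np.sqrt(2.0)
        expected = 0.5 * sd_resid / np.sqrt((0.5 * sd_resid) ** 2 + 25.0)
        assert r == pytest.approx(expected, abs=0.06)


class TestHierarchical:
    def test_positive_coupling_detected(self):
        df, _ = coupled_cohort(coupling=0.5, n_subjects=250, seed=5)
        out = residualize(df, fit_ladder_by(df, "activity"))
        res = hierarchical_test(out, "dorsal_caudate", "informative_value")
        assert res.b > 0 and res.p < 0.01
        assert res.aic_with < res.aic_without
        assert res.n == len(out)

    def test_shuffled_residuals_destroy_effect(self):
        df, _ = coupled_cohort(coupling=0.5, n_subjects=250, seed=6)
        out = residualize(df, fit_ladder_by(df, "activity"))
        rng = np.random.default_rng(0)
        out["activity_residual"] = rng.permutation(out["activity_residual"].to_numpy())
        res = hierarchical_test(out, "dorsal_caudate", "informative_value")
        assert abs(res.t) < 3.0  # permutation sanity: no systematic effect

    def test_battery_flags_against_adjusted_alpha(self):
        df, _ = coupled_cohort(coupling=0.6, n_subjects=200, seed=7)
        correction = mc_adjust(6, 0.66, 0.05)
        results = run_hierarchical_battery(residualize(df, fit_ladder_by(df, "activity")), correction)
        assert len(results) == 1
        assert results[0].significant_adjusted is not None


class TestCeilingFilter:
    def test_identity_without_ceiling(self):
        df, _ = coupled_cohort(n_subjects=50, seed=8)
        filtered, removed = ceiling_filter(df)
        assert len(filtered) == len(df) and removed == {}

    def test_all_at_ceiling_warns_empty(self):
        df, _ = coupled_cohort(n_subjects=20, seed=9)
        df = df.assign(performance=100.0)
        with pytest.warns(UserWarning):
            filtered, removed = ceiling_filter(df)
        assert filtered.empty and sum(removed.values()) == df[["subject_id", "wave"]].drop_duplicates().shape[0]

    def test_ceiling_fraction_matches_rate(self):
        cfg = CohortConfig(n_subjects=1000, rois=("dorsal_caudate",),
                           contrasts=("informative_value",), ceiling_rate=0.1,
                           performance_coef=TrajectoryCoef(b0=70.0))
        df, _ = generate_cohort(cfg, seed=10)
        filtered, removed = ceiling_filter(df)
        n_sw = df[["subject_id", "wave"]].drop_duplicates().shape[0]
        assert sum(removed.values()) / n_sw == pytest.approx(0.1, abs=0.02)
        assert len(filtered) < len(df)


class TestLagged:
    def test_identity_beta_one(self):
        df, _ = coupled_cohort(n_subjects=100, seed=11)
        dup = df.copy()
        dup["performance"] = dup["activity"]  # outcome == predictor at same wave
        res = lagged_prediction(dup, 1, 1, "dorsal_caudate", "informative_value")
        assert res.beta == pytest.approx(1.0)

    def test_independent_streams_null(self):
        """With no coupling and flat trajectories (no shared age structure)
        the cross-wave beta vanishes."""
        df, _ = coupled_cohort(
            coupling=0.0, n_subjects=400, seed=12,
            activity_coef=TrajectoryCoef(b0=2.0),
            performance_coef=TrajectoryCoef(b0=80.0),
            performance_intercept_sd=0.0,
        )
        res = lagged_prediction(df, 1, 2, "dorsal_caudate", "informative_value")
        assert abs(res.beta) < 0.15

    def test_persistent_coupling_gives_positive_beta(self):
        betas = []
        for seed in range(10):
            df, _ = coupled_cohort(coupling=0.6, n_subjects=250, seed=100 + seed)
            res = lagged_prediction(df, 1, 2, "dorsal_caudate", "informative_value")
            betas.append(res.beta)
        # coupling acts through the stable subject intercept -> positive sign
        assert np.mean(betas) > 0 and sum(b > 0 for b in betas) >= 9

    def test_small_sample_refused(self):
        df, _ = coupled_cohort(n_subjects=5, seed=13)
        with pytest.raises(SampleSizeError):
            lagged_prediction(df, 1, 2, "dorsal_caudate", "informative_value")

    def test_age_adjusted_variant_runs(self):
        df, _ = coupled_cohort(n_subjects=150, seed=14)
        res = lagged_prediction(df, 1, 2, "dorsal_caudate", "informative_value", age_adjust=True)
        assert res.age_adjusted and abs(res.beta) <= 1.5


class TestMCAdjust:
    def test_printed_adjusted_alpha(self):
        """Six correlated tests (r = 0.66) soften Bonferroni to alpha = 0.027."""
        corr = mc_adjust(6, 0.66, 0.05)
        assert corr.alpha_adjusted_rounded == 0.027
        assert corr.m_eff == pytest.approx(6 ** 0.34)

    def test_limits(self):
        assert mc_adjust(6, 0.0, 0.05).alpha_adjusted == pytest.approx(0.05 / 6)
        assert mc_adjust(6, 1.0, 0.05).alpha_adjusted == pytest.approx(0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mc_adjust(6, 1.2, 0.05)
        with pytest.raises(ValueError):
            mc_adjust(0, 0.5, 0.05)

    @given(
        k=st.integers(1, 20),
        r1=st.floats(0, 1),
        r2=st.floats(0, 1),
    )
    @settings(deadline=None, max_examples=60)
    def test_monotonicity_and_bounds(self, k, r1, r2):
        lo, hi = sorted([r1, r2])
        a_lo = mc_adjust(k, lo, 0.05)
        a_hi = mc_adjust(k, hi, 0.05)
        assert a_lo.alpha_adjusted <= a_hi.alpha_adjusted + 1e-12  # increasing in r
        assert 0.05 / k - 1e-12 <= a_lo.alpha_adjusted <= 0.05 + 1e-12
        assert 1.0 <= a_lo.m_eff <= k

    def test_decreasing_in_k(self):
        assert mc_adjust(10, 0.5, 0.05).alpha_adjusted < mc_adjust(3, 0.5, 0.05).alpha_adjusted


class TestMeanPairwiseCorrelation:
    def test_identical_variables(self):
        df, _ = coupled_cohort(n_subjects=50, seed=15)
        twin = df.copy()
        twin["contrast"] = "valence"
        both = pd.concat([df, twin], ignore_index=True)
        assert mean_pairwise_correlation(both) == pytest.approx(1.0)

    def test_independent_variables_near_zero(self, rng):
        rows = []
        for s in range(400):
            for roi in ("a", "b"):
                rows.append({"subject_id": s, "wave": 1, "roi": roi,
                             "contrast": "x", "activity": rng.normal()})
        assert abs(mean_pairwise_correlation(pd.DataFrame(rows))) < 0.1

    def test_constant_variable_skipped(self, rng):
        rows = []
        for s in range(30):
            rows.append({"subject_id": s, "wave": 1, "roi": "a", "contrast": "x",
                         "activity": rng.normal()})
            rows.append({"subject_id": s, "wave": 1, "roi": "b", "contrast": "x",
                         "activity": 1.0})
            rows.append({"subject_id": s, "wave": 1, "roi": "c", "contrast": "x",
                         "activity": rng.normal()})
        with pytest.warns(UserWarning):
            r = mean_pairwise_correlation(pd.DataFrame(rows))
        assert np.isfinite(r)
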