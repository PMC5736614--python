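import numpy as np
import pandas as pd
import pytest

from feedlearn.synthetic_cohort import CohortConfig, TrajectoryCoef, generate_cohort
from feedlearn.trajectory_models import (
    AgeBasis,
    SingleSubjectError,
    UndefinedICCError,
    compare_ladder,
    fit_ladder_by,
    fit_mixed,
    icc,
    peak_age,
    predict_trajectory,
)
from oracle_mixed import brute_force_ml


def quad_cohort(n_subjects=200, b1=0.2, b2=-0.05, u_sd=1.0, e_sd=1.0, seed=0, **kw):
    cfg = CohortConfig(
        n_subjects=n_subjects,
        rois=("dorsal_caudate",),
        contrasts=("informative_value",),
        activity_coef=TrajectoryCoef(b0=2.0, b1=b1, b2=b2),
        random_intercept_sd=u_sd,
        residual_sd=e_sd,
        ceiling_rate=0.0,
        **kw,
    )
    df, truth = generate_cohort(cfg, seed=seed)
    return df, cfg, truth


class TestBasis:
    def test_orthonormal_columns(self):
        ages = np.random.default_rng(0).uniform(8, 29, 400)
        basis = AgeBasis.fit(ages, 2)
        x = basis.transform(ages)
        gram = x.T @ x / len(ages)
        assert np.allclose(gram, np.eye(3), atol=1e-10)
        assert np.allclose(x[:, 0], 1.0)

    def test_raw_coefficient_roundtrip(self):
        ages = np.linspace(8, 29, 100)
        basis = AgeBasis.fit(ages, 2)
        beta = np.array([1.0, -0.5, 2.0])
        raw = basis.raw_coefficients(beta)
        direct = basis.transform(ages) @ beta
        poly = raw[0] + raw[1] * ages + raw[2] * ages**2
        assert np.allclose(direct, poly, atol=1e-8)


class TestFitMixed:
    def test_matches_brute_force_on_tiny_data(self):
        """Profile-likelihood grid search over the dense covariance
        reproduces the fitted log-likelihood on <= 5 subjects x 3 waves."""
        rng = np.random.default_rng(7)
        for degree in (0, 1, 2):
            rows = []
            for s in range(5):
                u = rng.normal(0, 1)
                for w in range(3):
                    age = 8 + 4 * s + 2 * w
                    rows.append({"subject_id": s, "age": age,
                                 "y": 1 + 0.1 * age + u + rng.normal(0, 0.8)})
            df = pd.DataFrame(rows)
            fit = fit_mixed(df, "y", degree)
            assert fit.loglik == pytest.approx(brute_force_ml(df, "y", degree), abs=1e-4)

    def test_matches_statsmodels_mixedlm(self):
        """Independent cross-check against statsmodels MixedLM (full ML)."""
        import statsmodels.formula.api as smf

        df, _, _ = quad_cohort(n_subjects=60, seed=3)
        fit = fit_mixed(df, "activity", 2)
        d = df.copy()
        d["c"] = d["age"] - d["age"].mean()
        m = smf.mixedlm("activity ~ c + I(c**2)", d, groups=d["subject_id"]).fit(reml=False)
        assert fit.loglik == pytest.approx(m.llf, abs=1e-4)
        assert fit.var_e == pytest.approx(m.scale, rel=1e-3)
        assert fit.var_u == pytest.approx(float(m.cov_re.iloc[0, 0]), rel=1e-3)
        # fixed-effect curves agree even though the bases differ
        grid = np.linspace(9, 28, 7)
        sm_curve = m.params["Intercept"] + m.params["c"] * (grid - df["age"].mean()) \
            + m.params["I(c ** 2)"] * (grid - df["age"].mean()) ** 2
        assert np.allclose(fit.fixed_prediction(grid), sm_curve, atol=1e-3)

    def test_aic_identity(self):
        df, _, _ = quad_cohort(n_subjects=40, seed=1)
        for degree in (0, 1, 2):
            fit = fit_mixed(df, "activity", degree)
            assert fit.aic == pytest.approx(2 * (degree + 3) - 2 * fit.loglik)

    def test_recovers_generating_coefficients(self):
        df, cfg, _ = quad_cohort(n_subjects=500, seed=21)
        fit = fit_mixed(df, "activity", 2)
        raw = fit.raw_coefficients
        # convert truth (centered at cfg.age_center) to the raw-age polynomial
        tc = cfg.activity_coefficients()[("dorsal_caudate", "informative_value")]
        a0 = tc.b0 - tc.b1 * cfg.age_center + tc.b2 * cfg.age_center**2
        a1 = tc.b1 - 2 * tc.b2 * cfg.age_center
        a2 = tc.b2
        # compare on the quadratic/linear terms at 3 SEs via the basis map
        grid = np.linspace(9, 28, 15)
        truth_curve = a0 + a1 * grid + a2 * grid**2
        curve = predict_trajectory(fit, grid)
        assert np.all(curve.mean - truth_curve < 6 * (curve.upper - curve.mean) / 1.96)
        assert abs(raw[2] - a2) < 0.01

    def test_single_subject_rejected(self):
        df = pd.DataFrame({"subject_id": [1, 1, 1], "age": [8, 10, 12], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(SingleSubjectError):
            fit_mixed(df, "y", 0)

    def test_constant_outcome_degenerate(self):
        df = pd.DataFrame({"subject_id": np.repeat(np.arange(10), 3),
                           "age": np.tile([8.0, 10.0, 12.0], 10), "y": 5.0})
        fit = fit_mixed(df, "y", 0)
        assert np.isfinite(fit.loglik)
        assert fit.var_e <= 1e-10 and fit.beta[0] == pytest.approx(5.0)

    def test_basis_invariance_of_curves(self):
        """Predicted curves agree between orthonormal and raw-centered bases."""
        df, _, _ = quad_cohort(n_subjects=80, seed=5)
        grid = np.linspace(9, 28, 11)
        f_orth = fit_mixed(df, "activity", 2, basis_kind="orthonormal")
        f_raw = fit_mixed(df, "activity", 2, basis_kind="raw_centered")
        assert np.allclose(f_orth.fixed_prediction(grid), f_raw.fixed_prediction(grid), atol=1e-5)
        assert f_orth.loglik == pytest.approx(f_raw.loglik, abs=1e-6)


class TestLadder:
    def test_loglik_nesting_and_determinism(self):
        for seed in (0, 1, 2):
            df, _, _ = quad_cohort(n_subjects=30, seed=seed)
            comp = compare_ladder(df, "activity")
            lls = [comp.fits[d].loglik for d in (0, 1, 2)]
            assert lls[0] <= lls[1] + 1e-8 and lls[1] <= lls[2] + 1e-8
            comp2 = compare_ladder(df, "activity")
            assert [comp2.fits[d].aic for d in (0, 1, 2)] == [comp.fits[d].aic for d in (0, 1, 2)]

    def test_strong_quadratic_selected(self):
        df, _, _ = quad_cohort(n_subjects=250, b1=0.25, b2=-0.05, seed=13)
        assert compare_ladder(df, "activity").selected_degree == 2

    def test_selection_rules_differ_when_linear_step_flat(self):
        """A mid-range peak hides from the linear step: forward_stop stays at
        0/1 only if its own step fails, any_step can still pick the quadratic."""
        df, _, _ = quad_cohort(n_subjects=250, b1=0.0, b2=-0.05, seed=17)
        fwd = compare_ladder(df, "activity", rule="forward_stop")
        any_ = compare_ladder(df, "activity", rule="any_step")
        assert any_.selected_degree == 2
        assert any_.lrt_p[2] < 0.05
        aic = compare_ladder(df, "activity", rule="aic")
        assert aic.selected_degree == 2

    def test_fit_ladder_by_strata(self):
        cfg = CohortConfig(n_subjects=60, ceiling_rate=0.0)
        df, _ = generate_cohort(cfg, seed=4)
        out = fit_ladder_by(df, "activity")
        assert set(out) == set(cfg.strata)


class TestTrajectoryAndPeak:
    def test_degree0_flat_curve(self):
        df, _, _ = quad_cohort(n_subjects=40, seed=2)
        fit = fit_mixed(df, "activity", 0)
        curve = predict_trajectory(fit, np.linspace(10, 25, 5))
        assert np.allclose(curve.mean, curve.mean[0])
        assert np.all(curve.lower <= curve.mean) and np.all(curve.mean <= curve.upper)

    def test_band_shrinks_with_n(self):
        small, _, _ = quad_cohort(n_subjects=100, seed=6)
        large, _, _ = quad_cohort(n_subjects=1000, seed=6)
        grid = np.linspace(10, 27, 9)
        c_small = predict_trajectory(fit_mixed(small, "activity", 2), grid)
        c_large = predict_trajectory(fit_mixed(large, "activity", 2), grid)
        assert np.mean(c_large.upper - c_large.lower) < np.mean(c_small.upper - c_small.lower)

    def test_extrapolation_flag(self):
        df, _, _ = quad_cohort(n_subjects=40, seed=2)
        fit = fit_mixed(df, "activity", 2)
        assert predict_trajectory(fit, np.array([40.0])).extrapolated
        assert not predict_trajectory(fit, np.array([15.0])).extrapolated

    def test_peak_vertex_formula(self):
        """Noise-free parabola with vertex at 20: peak = -b1/(2 b2)."""
        rng = np.random.default_rng(0)
        ages = rng.uniform(8, 29, 600)
        subj = np.arange(600) // 3
        y = 10 + 2.0 * ages - 0.05 * ages**2 + rng.normal(0, 0.01, 600)
        df = pd.DataFrame({"subject_id": subj, "age": ages, "y": y})
        fit = fit_mixed(df, "y", 2)
        pk = peak_age(fit, rng=np.random.default_rng(1))
        assert pk.valid and pk.peak_age == pytest.approx(20.0, abs=0.05)
        assert pk.ci_low <= pk.peak_age <= pk.ci_high

    def test_convex_fit_flagged_invalid(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(8, 29, 300)
        y = 1 + 0.05 * (ages - 18) ** 2 + rng.normal(0, 0.5, 300)
        df = pd.DataFrame({"subject_id": np.arange(300) // 3, "age": ages, "y": y})
        pk = peak_age(fit_mixed(df, "y", 2), rng=np.random.default_rng(0))
        assert not pk.valid and pk.peak_age is None

    def test_peak_requires_quadratic_fit(self):
        df, _, _ = quad_cohort(n_subjects=30, seed=0)
        with pytest.raises(ValueError):
            peak_age(fit_mixed(df, "activity", 1))


class TestICC:
    def test_extremes(self):
        df_no_u, _, _ = quad_cohort(n_subjects=200, b1=0, b2=0, u_sd=0.0, e_sd=1.0, seed=8)
        assert icc(df_no_u, "activity") < 0.05
        df_no_e, _, _ = quad_cohort(n_subjects=200, b1=0, b2=0, u_sd=1.0, e_sd=0.01, seed=8)
        assert icc(df_no_e, "activity") > 0.95

    def test_equal_variances_near_half(self):
        df, _, _ = quad_cohort(n_subjects=400, b1=0, b2=0, u_sd=1.0, e_sd=1.0, seed=9)
        assert icc(df, "activity") == pytest.approx(0.5, abs=0.06)

    def test_zero_variance_undefined(self):
        df = pd.DataFrame({"subject_id": np.repeat(np.arange(5), 3),
                           "age": np.tile([8.0, 10.0, 12.0], 5), "y": 1.0})
        with pytest.raises(UndefinedICCError):
            icc(df, "y")
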