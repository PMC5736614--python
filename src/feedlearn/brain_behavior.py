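"""Linking ROI activity to learning performance.

The chain of analyses implemented here:

1. **Residualize** each ROI-contrast activity series against its selected
   age trajectory (fixed effects only; the subject intercepts carry exactly
   the between-subject signal the brain-behaviour test needs).
2. **Hierarchical mixed regression** — does adding the activity residual to
   the quadratic age model of performance improve prediction?  Reported as
   the residual coefficient with its Wald test and the AIC with/without.
3. **Ceiling sensitivity** — repeat after removing subject-waves that scored
   exactly 100%.
4. **Lagged prediction** — standardized regression of wave-(w+k) performance
   on wave-w activity across subjects present at both waves.
5. **Multiplicity correction** for correlated tests: the effective number of
   tests is m_eff = k^(1 - rbar) where rbar is the mean pairwise correlation
   among the tested variables, and the family alpha is Bonferroni-divided by
   m_eff (k = 6 tests, rbar = 0.66 gives the adjusted alpha of 0.027).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .trajectory_models import ModelComparison, ModelFit, fit_mixed

Stratum = tuple[str, str]


class SampleSizeError(ValueError):
    """Too few complete observation pairs for a meaningful regression."""


def _fit_of(best: Union[ModelFit, ModelComparison]) -> ModelFit:
    return best.selected if isinstance(best, ModelComparison) else best


def residualize(
    rows: pd.DataFrame,
    best_fits: Mapping[Stratum, Union[ModelFit, ModelComparison]],
    activity_col: str = "activity",
) -> pd.DataFrame:
    """Activity minus the fixed-effect prediction of its selected age model.

    Random intercepts are *not* subtracted.  Strata without a supplied fit
    are skipped with a warning.
    """
    frames = []
    for (roi, contrast), grp in rows.groupby(["roi", "contrast"], sort=False):
        if (roi, contrast) not in best_fits:
            warnings.warn(f"no age model for stratum ({roi}, {contrast}); skipped")
            continue
        fit = _fit_of(best_fits[(roi, contrast)])
        out = grp.copy()
        out["activity_residual"] = (
            grp[activity_col].to_numpy(dtype=float) - fit.fixed_prediction(grp["age"].to_numpy())
        )
        frames.append(out)
    if not frames:
        return rows.iloc[0:0].assign(activity_residual=[])
    return pd.concat(frames, ignore_index=True)


@dataclass
class HierarchicalResult:
    """Residual activity term added to the quadratic age model of performance."""

    roi: str
    contrast: str
    b: float  # unstandardized coefficient on the activity residual
    se: float
    t: float
    p: float
    aic_with: float
    aic_without: float
    n: int
    n_subjects: int
    significant_unadjusted: Optional[bool] = None
    significant_adjusted: Optional[bool] = None

    @property
    def delta_aic(self) -> float:
        return self.aic_with - self.aic_without


def hierarchical_test(
    residual_rows: pd.DataFrame,
    roi: str,
    contrast: str,
    performance_col: str = "performance",
) -> HierarchicalResult:
    """Mixed model performance ~ age + age^2 + activity_residual + (1|subject).

    ``residual_rows`` is the residualized long table restricted (internally)
    to one stratum; performance joins on subject-wave implicitly because the
    long table carries it per row.
    """
    sub = residual_rows[(residual_rows["roi"] == roi) & (residual_rows["contrast"] == contrast)]
    sub = sub.dropna(subset=[performance_col, "activity_residual"])
    if sub["activity_residual"].std(ddof=0) <= 1e-12:
        raise ValueError(f"activity_residual is constant in stratum ({roi}, {contrast})")
    with_fit = fit_mixed(sub, performance_col, degree=2, extra_cols=("activity_residual",))
    without_fit = fit_mixed(sub, performance_col, degree=2)
    b = float(with_fit.beta[-1])
    se = float(np.sqrt(with_fit.cov_beta[-1, -1]))
    t = b / se
    p = float(2.0 * stats.norm.sf(abs(t)))
    return HierarchicalResult(
        roi=roi,
        contrast=contrast,
        b=b,
        se=se,
        t=t,
        p=p,
        aic_with=with_fit.aic,
        aic_without=without_fit.aic,
        n=with_fit.n_obs,
        n_subjects=with_fit.n_subjects,
    )


def run_hierarchical_battery(
    residual_rows: pd.DataFrame,
    correction: "MCCorrection",
    performance_col: str = "performance",
) -> list[HierarchicalResult]:
    """One hierarchical test per stratum, flagged against the adjusted alpha.

    Results significant at the family alpha but not at the adjusted alpha
    keep ``significant_unadjusted=True, significant_adjusted=False`` — the
    "significant before but not after correction" report.
    """
    results = []
    for roi, contrast in residual_rows[["roi", "contrast"]].drop_duplicates().itertuples(index=False):
        res = hierarchical_test(residual_rows, roi, contrast, performance_col)
        res.significant_unadjusted = res.p < correction.alpha_family
        res.significant_adjusted = res.p < correction.alpha_adjusted
        results.append(res)
    return results


def ceiling_filter(
    rows: pd.DataFrame,
    performance_col: str = "performance",
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Drop subject-waves scoring exactly 100%; report removals per wave."""
    sw = rows[["subject_id", "wave", performance_col]].drop_duplicates(["subject_id", "wave"])
    at_ceiling = sw[sw[performance_col] == 100.0]
    removed_per_wave = at_ceiling.groupby("wave").size().to_dict()
    if len(at_ceiling) == len(sw) and len(sw) > 0:
        warnings.warn("every subject-wave is at ceiling; filtered table is empty")
    keys = set(zip(at_ceiling["subject_id"], at_ceiling["wave"]))
    mask = [
        (s, w) not in keys for s, w in zip(rows["subject_id"], rows["wave"])
    ]
    return rows[np.asarray(mask)], {int(w): int(n) for w, n in removed_per_wave.items()}


@dataclass
class LaggedResult:
    predictor_wave: int
    outcome_wave: int
    roi: str
    contrast: str
    beta: float  # standardized
    p: float
    n: int
    age_adjusted: bool


def lagged_prediction(
    rows: pd.DataFrame,
    predictor_wave: int,
    outcome_wave: int,
    roi: str,
    contrast: str,
    activity_col: str = "activity",
    performance_col: str = "performance",
    age_adjust: bool = False,
    min_pairs: int = 10,
) -> LaggedResult:
    """Predict later-wave performance from earlier-wave activity.

    Both variables are standardized over the complete pairs, so the simple
    regression slope is the standardized beta.  With ``age_adjust`` the
    predictor-wave age joins as a covariate and beta is the partial
    standardized coefficient.
    """
    pred = rows[
        (rows["wave"] == predictor_wave) & (rows["roi"] == roi) & (rows["contrast"] == contrast)
    ][["subject_id", "age", activity_col]]
    outc = rows[rows["wave"] == outcome_wave][["subject_id", performance_col]].drop_duplicates(
        "subject_id"
    )
    merged = pred.merge(outc, on="subject_id").dropna()
    n = len(merged)
    if n < min_pairs:
        raise SampleSizeError(
            f"only {n} complete pairs between waves {predictor_wave} and {outcome_wave}"
        )

    def _std(v):
        v = np.asarray(v, dtype=float)
        s = v.std(ddof=1)
        if s == 0:
            raise ValueError("constant variable in lagged regression")
        return (v - v.mean()) / s

    x = _std(merged[activity_col])
    y = _std(merged[performance_col])
    if age_adjust:
        import statsmodels.api as sm

        design = sm.add_constant(np.column_stack([x, _std(merged["age"])]))
        ols = sm.OLS(y, design).fit()
        beta, p = float(ols.params[1]), float(ols.pvalues[1])
    else:
        res = stats.linregress(x, y)
        beta, p = float(res.slope), float(res.pvalue)
    return LaggedResult(predictor_wave, outcome_wave, roi, contrast, beta, p, n, age_adjust)


# ---------------------------------------------------------------------------
# multiplicity correction for correlated variables


@dataclass(frozen=True)
class MCCorrection:
    k: int
    r_bar: float
    alpha_family: float
    m_eff: float
    alpha_adjusted: float

    @property
    def alpha_adjusted_rounded(self) -> float:
        """Adjusted alpha at reporting precision (3 decimals)."""
        return round(self.alpha_adjusted, 3)


def mc_adjust(k: int, r_bar: float, alpha_family: float = 0.05) -> MCCorrection:
    """Bonferroni correction softened for correlated tests.

    The effective number of tests is m_eff = k^(1 - r_bar): with independent
    variables (r_bar=0) this is plain Bonferroni alpha/k, with perfectly
    correlated variables (r_bar=1) a single effective test.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 <= r_bar <= 1.0:
        raise ValueError("r_bar must be in [0, 1]")
    if not 0.0 < alpha_family < 1.0:
        raise ValueError("alpha_family must be in (0, 1)")
    m_eff = float(k ** (1.0 - r_bar))
    return MCCorrection(k=k, r_bar=r_bar, alpha_family=alpha_family, m_eff=m_eff,
                        alpha_adjusted=alpha_family / m_eff)


def mean_pairwise_correlation(
    rows: pd.DataFrame,
    value_col: str = "activity",
    var_cols: Sequence[str] = ("roi", "contrast"),
    index_cols: Sequence[str] = ("subject_id", "wave"),
) -> float:
    """Mean Pearson correlation over all variable pairs (complete pairs only).

    Variables are the distinct combinations of ``var_cols``; observations are
    ``index_cols`` units.  Constant variables are skipped with a warning.
    """
    wide = rows.pivot_table(index=list(index_cols), columns=list(var_cols), values=value_col)
    cols = list(wide.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 variables for pairwise correlations")
    corrs = []
    for a, b in itertools.combinations(cols, 2):
        pair = wide[[a, b]].dropna()
        sa, sb = pair[a].std(ddof=1), pair[b].std(ddof=1)
        if len(pair) < 3 or sa == 0 or sb == 0 or not np.isfinite(sa * sb):
            warnings.warn(f"skipping constant/degenerate pair {a} ~ {b}")
            continue
        corrs.append(float(pair[a].corr(pair[b])))
    if not corrs:
        raise ValueError("no valid variable pairs")
    return float(np.mean(corrs))
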