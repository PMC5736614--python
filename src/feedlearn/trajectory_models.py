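"""Random-intercept mixed models for developmental trajectories.

The analysis fits, for each outcome, a ladder of three nested models:

    degree 0   outcome ~ 1            + (1 | subject)
    degree 1   outcome ~ age          + (1 | subject)
    degree 2   outcome ~ age + age^2  + (1 | subject)

compared by AIC and by likelihood-ratio tests on chi-square(1) per added
fixed effect.  Estimation is full maximum likelihood (never REML) because
the compared models differ in their fixed effects.

The age polynomial is fitted on an orthonormal basis built from the observed
ages (numerically well conditioned and step-wise interpretable); predicted
curves and peak ages are basis-free, and every fit also carries its
coefficients mapped back to the raw age scale.

The ML fit exploits the model's structure: for a fixed variance ratio
lambda = var_u / var_e the GLS coefficients and the residual variance have
closed forms via the Sherman-Morrison identity on the compound-symmetric
within-subject covariance, leaving a one-dimensional profiled log-likelihood
in lambda that is maximised deterministically (coarse log-grid, then bounded
Brent refinement to ~1e-10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

SELECTION_RULES = ("forward_stop", "any_step", "aic")


class SingleSubjectError(ValueError):
    """Random intercept unidentifiable with fewer than two subjects."""


class UndefinedICCError(ValueError):
    """Total variance is zero; the ICC is undefined."""


# ---------------------------------------------------------------------------
# age basis


@dataclass(frozen=True)
class AgeBasis:
    """Polynomial age basis frozen on the fitting sample.

    ``kind='orthonormal'``: columns are the QR-orthonormalised monomials of
    the standardised age (column 0 is the constant 1), scaled so each has
    unit sample mean square.  ``kind='raw_centered'``: plain centered
    monomials [1, a-abar, (a-abar)^2].  Either basis can be evaluated at new
    ages, and fitted coefficients can be mapped to the raw age polynomial.
    """

    degree: int
    kind: str
    mean: float
    scale: float
    rinv: np.ndarray  # maps monomials of standardized age to basis columns
    age_min: float
    age_max: float

    @staticmethod
    def fit(ages: np.ndarray, degree: int, kind: str = "orthonormal") -> "AgeBasis":
        ages = np.asarray(ages, dtype=float)
        if not np.all(np.isfinite(ages)):
            raise ValueError("ages must be finite")
        m = float(ages.mean())
        s = float(ages.std()) or 1.0
        if kind == "raw_centered":
            s = 1.0
        z = (ages - m) / s
        v = np.vander(z, degree + 1, increasing=True)
        if kind == "orthonormal":
            q, r = np.linalg.qr(v)
            signs = np.sign(np.diag(r))
            signs[signs == 0] = 1.0
            r = r * signs[:, None]
            rinv = np.linalg.inv(r) * np.sqrt(len(ages))
        elif kind == "raw_centered":
            rinv = np.eye(degree + 1)
        else:
            raise ValueError(f"unknown basis kind {kind!r}")
        return AgeBasis(degree, kind, m, s, rinv, float(ages.min()), float(ages.max()))

    def transform(self, ages: np.ndarray) -> np.ndarray:
        z = (np.asarray(ages, dtype=float) - self.mean) / self.scale
        return np.vander(z, self.degree + 1, increasing=True) @ self.rinv

    def raw_coefficients(self, beta: np.ndarray) -> np.ndarray:
        """Map basis coefficients to the raw-age polynomial (ascending)."""
        cz = self.rinv @ np.asarray(beta, dtype=float)[: self.degree + 1]
        poly_z = np.polynomial.Polynomial(cz)
        shift = np.polynomial.Polynomial([-self.mean / self.scale, 1.0 / self.scale])
        return poly_z(shift).coef


# ---------------------------------------------------------------------------
# ML random-intercept fit


@dataclass
class ModelFit:
    """One fitted random-intercept model on the age ladder."""

    degree: int
    beta: np.ndarray  # basis coefficients (+ extra covariates, in order)
    cov_beta: np.ndarray
    var_u: float  # random-intercept variance
    var_e: float  # residual variance
    loglik: float
    aic: float
    n_obs: int
    n_subjects: int
    basis: AgeBasis
    extra_names: tuple[str, ...] = ()
    converged: bool = True
    singular_u: bool = False

    @property
    def k_params(self) -> int:
        return len(self.beta) + 2

    @property
    def raw_coefficients(self) -> np.ndarray:
        """Fixed-effect age polynomial on the raw age scale (ascending)."""
        return self.basis.raw_coefficients(self.beta)

    def fixed_prediction(self, ages: np.ndarray) -> np.ndarray:
        """Fixed-effects (population mean) prediction; extras held at zero."""
        x = self.basis.transform(ages)
        return x @ self.beta[: self.basis.degree + 1]


def _ml_random_intercept(x: np.ndarray, y: np.ndarray, group_slices):
    """Full-ML fit of y = X b + u_group + e; returns the profiled solution.

    Per-group sufficient statistics are stacked once so each evaluation of
    the profiled log-likelihood is a handful of vectorized contractions.
    """
    n, p = x.shape
    sx = np.stack([x[sl].sum(axis=0) for sl in group_slices])  # (G, p)
    sy = np.array([y[sl].sum() for sl in group_slices])  # (G,)
    ni = np.array([sl.stop - sl.start for sl in group_slices], dtype=float)
    sxx_tot = x.T @ x
    sxy_tot = x.T @ y
    syy_tot = float(y @ y)

    def negloglik_at(lam: float):
        w = lam / (1.0 + lam * ni)  # (G,)
        a = sxx_tot - np.einsum("g,gi,gj->ij", w, sx, sx)
        b = sxy_tot - (w * sy) @ sx
        q = syy_tot - float(w @ (sy * sy))
        logdet = float(np.log1p(lam * ni).sum())
        try:
            beta = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(a, b, rcond=None)[0]
        rss = max(q - b @ beta, 0.0)
        sigma2 = max(rss / n, 1e-12)
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + n + logdet)
        return -ll, beta, a, sigma2

    def objective(log_lam: float) -> float:
        return negloglik_at(np.exp(log_lam))[0]

    grid = np.linspace(-10.0, 8.0, 37)
    vals = [objective(g) for g in grid]
    j = int(np.argmin(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    cand = [(res.fun, float(np.exp(res.x))), (vals[j], float(np.exp(grid[j])))]
    nll0, *_ = negloglik_at(0.0)
    cand.append((nll0, 0.0))
    nll_best, lam_best = min(cand, key=lambda t: t[0])

    _, beta, a, sigma2 = negloglik_at(lam_best)
    cov_beta = sigma2 * np.linalg.inv(a)
    return beta, cov_beta, lam_best * sigma2, sigma2, -nll_best


def fit_mixed(
    rows: pd.DataFrame,
    outcome: str,
    degree: int,
    subject_col: str = "subject_id",
    age_col: str = "age",
    basis_kind: str = "orthonormal",
    extra_cols: Sequence[str] = (),
) -> ModelFit:
    """ML fit of ``outcome ~ age polynomial (+ extras) + (1 | subject)``.

    ``extra_cols`` appends observed covariate columns (e.g. activity
    residuals) after the age terms; their coefficients share the basis-free
    raw scale of the data.
    """
    if degree not in (0, 1, 2):
        raise ValueError("degree must be 0, 1 or 2")
    df = rows[[subject_col, age_col, outcome, *extra_cols]].dropna()
    subjects, codes = np.unique(df[subject_col].to_numpy(), return_inverse=True)
    if len(subjects) < 2:
        raise SingleSubjectError("need at least 2 subjects to identify the random intercept")
    if len(df) < len(subjects):
        raise ValueError("fewer observations than subjects")
    order = np.argsort(codes, kind="stable")
    codes = codes[order]
    ages = df[age_col].to_numpy(dtype=float)[order]
    y = df[outcome].to_numpy(dtype=float)[order]

    basis = AgeBasis.fit(ages, degree, basis_kind)
    x = basis.transform(ages)
    if extra_cols:
        x = np.column_stack([x, df[list(extra_cols)].to_numpy(dtype=float)[order]])

    boundaries = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries, [len(codes)]])
    slices = [slice(a, b) for a, b in zip(starts, stops)]

    beta, cov_beta, var_u, var_e, ll = _ml_random_intercept(x, y, slices)
    k = x.shape[1] + 2
    return ModelFit(
        degree=degree,
        beta=beta,
        cov_beta=cov_beta,
        var_u=var_u,
        var_e=var_e,
        loglik=ll,
        aic=2.0 * k - 2.0 * ll,
        n_obs=len(y),
        n_subjects=len(subjects),
        basis=basis,
        extra_names=tuple(extra_cols),
        singular_u=var_u <= 1e-10,
    )


# ---------------------------------------------------------------------------
# ladder comparison


@dataclass
class ModelComparison:
    """No-age / linear / quadratic ladder with LRT p-values and selection."""

    fits: dict[int, ModelFit]
    lrt_p: dict[int, float]  # p for the step up to each degree (1 and 2)
    selected_degree: int
    rule: str
    alpha: float

    @property
    def selected(self) -> ModelFit:
        return self.fits[self.selected_degree]

    def select(self, rule: str, alpha: Optional[float] = None) -> int:
        """Re-derive the selected degree under another rule from the stored
        fits (no refitting)."""
        if rule not in SELECTION_RULES:
            raise ValueError(f"rule must be one of {SELECTION_RULES}")
        alpha = self.alpha if alpha is None else alpha
        if rule == "aic":
            return min(self.fits, key=lambda d: self.fits[d].aic)
        if rule == "any_step":
            if self.lrt_p[2] < alpha:
                return 2
            return 1 if self.lrt_p[1] < alpha else 0
        selected = 0
        if self.lrt_p[1] < alpha:
            selected = 1
            if self.lrt_p[2] < alpha:
                selected = 2
        return selected

    def summary(self) -> dict:
        return {
            "aic": {d: f.aic for d, f in self.fits.items()},
            "loglik": {d: f.loglik for d, f in self.fits.items()},
            "lrt_p": dict(self.lrt_p),
            "selected_degree": self.selected_degree,
            "rule": self.rule,
        }


def compare_ladder(
    rows: pd.DataFrame,
    outcome: str,
    rule: str = "forward_stop",
    alpha: float = 0.05,
    subject_col: str = "subject_id",
    age_col: str = "age",
) -> ModelComparison:
    """Fit degrees 0-2 and select a trajectory shape.

    Step-up LRT p-values use chi-square(1) on twice the log-likelihood gain.
    Selection rules:

    * ``forward_stop`` (default) — climb the ladder while each step is
      significant; stop at the first non-significant step.  Holds the
      family type-I rate at alpha under the no-age null.
    * ``any_step`` — highest degree whose own step is significant, even if a
      lower step was not (a quadratic peak can be invisible to the linear
      step when the peak sits mid-range).
    * ``aic`` — lowest AIC regardless of the LRTs.
    """
    if rule not in SELECTION_RULES:
        raise ValueError(f"rule must be one of {SELECTION_RULES}")
    fits = {
        d: fit_mixed(rows, outcome, d, subject_col=subject_col, age_col=age_col)
        for d in (0, 1, 2)
    }
    lrt_p = {}
    for d in (1, 2):
        stat = max(2.0 * (fits[d].loglik - fits[d - 1].loglik), 0.0)
        lrt_p[d] = float(stats.chi2.sf(stat, df=1))

    comp = ModelComparison(fits=fits, lrt_p=lrt_p, selected_degree=0, rule=rule, alpha=alpha)
    comp.selected_degree = comp.select(rule)
    return comp


def fit_ladder_by(
    rows: pd.DataFrame,
    outcome: str,
    by: Sequence[str] = ("roi", "contrast"),
    **kwargs,
) -> dict[tuple, ModelComparison]:
    """Run the ladder independently per stratum (e.g. per ROI x contrast)."""
    out = {}
    for key, grp in rows.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        out[key] = compare_ladder(grp, outcome, **kwargs)
    return out


# ---------------------------------------------------------------------------
# trajectories, peaks, ICC


@dataclass
class TrajectoryCurve:
    ages: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    extrapolated: bool


def predict_trajectory(fit: ModelFit, ages: np.ndarray) -> TrajectoryCurve:
    """Fixed-effects mean curve with a pointwise delta-method 95% band."""
    ages = np.asarray(ages, dtype=float)
    p_age = fit.basis.degree + 1
    x = fit.basis.transform(ages)
    mean = x @ fit.beta[:p_age]
    se = np.sqrt(np.einsum("ij,jk,ik->i", x, fit.cov_beta[:p_age, :p_age], x))
    z = stats.norm.ppf(0.975)
    extrapolated = bool(ages.min() < fit.basis.age_min or ages.max() > fit.basis.age_max)
    return TrajectoryCurve(ages, mean, mean - z * se, mean + z * se, extrapolated)


@dataclass
class PeakEstimate:
    peak_age: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    valid: bool
    n_boot_valid: int = 0


def peak_age(
    fit: ModelFit,
    n_boot: int = 2000,
    rng: Optional[np.random.Generator] = None,
) -> PeakEstimate:
    """Vertex of a quadratic trajectory with a parametric-bootstrap CI.

    The estimate is valid only when the raw quadratic coefficient is
    negative and the vertex lies inside the observed age range.  The CI is
    the 2.5/97.5 percentile of vertices over coefficient draws from the
    fitted sampling distribution (concave draws only).
    """
    if fit.degree != 2:
        raise ValueError("peak age requires a degree-2 fit")
    if rng is None:
        rng = np.random.default_rng(0)
    c = fit.raw_coefficients
    if c[2] >= 0:
        return PeakEstimate(None, None, None, valid=False)
    peak = float(-c[1] / (2.0 * c[2]))
    valid = fit.basis.age_min <= peak <= fit.basis.age_max

    p_age = fit.basis.degree + 1
    draws = rng.multivariate_normal(
        fit.beta[:p_age], fit.cov_beta[:p_age, :p_age], size=n_boot
    )
    peaks = []
    for b in draws:
        cb = fit.basis.raw_coefficients(b)
        if cb[2] < 0:
            peaks.append(-cb[1] / (2.0 * cb[2]))
    if len(peaks) >= max(20, n_boot // 10):
        lo, hi = np.percentile(peaks, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    return PeakEstimate(peak, float(lo), float(hi), valid=valid, n_boot_valid=len(peaks))


def icc(
    rows: pd.DataFrame,
    outcome: str,
    subject_col: str = "subject_id",
    age_col: str = "age",
) -> float:
    """Intra-class correlation from the degree-0 mixed fit:
    between-subject variance / total variance."""
    fit = fit_mixed(rows, outcome, degree=0, subject_col=subject_col, age_col=age_col)
    total = fit.var_u + fit.var_e
    if total <= 1e-10:
        raise UndefinedICCError("total variance is (numerically) zero")
    return float(fit.var_u / total)
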