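"""Brute-force ML reference for the random-intercept model.

Builds the dense marginal covariance sigma_e^2 I + sigma_u^2 J per subject
and maximises the exact multivariate-normal log-likelihood (GLS beta
profiled out) by direct search over the variance-ratio, using plain dense
linear algebra throughout.  Only suitable for tiny problems.
"""

import numpy as np
from scipy import optimize


def _dense_loglik(x, y, groups, lam):
    """Profiled log-likelihood at variance ratio lam = var_u / var_e."""
    n = len(y)
    blocks = []
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        blocks.append(idx)
    # GLS with V = I + lam * J per block (up to sigma_e^2)
    vinvs = {tuple(idx): np.linalg.inv(np.eye(len(idx)) + lam * np.ones((len(idx), len(idx))))
             for idx in blocks}
    xtvx = np.zeros((x.shape[1], x.shape[1]))
    xtvy = np.zeros(x.shape[1])
    for idx in blocks:
        vi = vinvs[tuple(idx)]
        xi, yi = x[idx], y[idx]
        xtvx += xi.T @ vi @ xi
        xtvy += xi.T @ vi @ yi
    beta = np.linalg.solve(xtvx, xtvy)
    rss = 0.0
    logdet = 0.0
    for idx in blocks:
        vi = vinvs[tuple(idx)]
        r = y[idx] - x[idx] @ beta
        rss += r @ vi @ r
        sign, ld = np.linalg.slogdet(np.eye(len(idx)) + lam * np.ones((len(idx), len(idx))))
        logdet += ld
    sigma2 = rss / n
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdet)


def brute_force_ml(df, outcome, degree, subject_col="subject_id", age_col="age"):
    """Maximised ML log-likelihood over a fine variance-ratio search.

    Uses raw centered monomials as the fixed-effect design; the maximum
    log-likelihood is basis-invariant, so it is directly comparable with a
    fit on any basis spanning the same polynomial space.
    """
    ages = df[age_col].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    groups = df[subject_col].to_numpy()
    c = ages - ages.mean()
    x = np.column_stack([c**d for d in range(degree + 1)])

    def neg(log_lam):
        return -_dense_loglik(x, y, groups, np.exp(log_lam))

    grid = np.linspace(-12, 8, 81)
    vals = [neg(g) for g in grid]
    j = int(np.argmin(vals))
    res = optimize.minimize_scalar(
        neg, bounds=(grid[max(j - 1, 0)], grid[min(j + 1, len(grid) - 1)]),
        method="bounded", options={"xatol": 1e-12},
    )
    best = max(-res.fun, -vals[j])
    boundary = _dense_loglik(x, y, groups, 0.0)
    return max(best, boundary)
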