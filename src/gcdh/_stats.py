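"""Shared least-squares machinery.

Every association fit in the package is an OLS of the trait on one genetic
predictor plus a fixed covariate block (intercept, sex, age, PCs). Fitting
thousands of such models is the hot path of the genome scan, so the
covariate block is orthonormalised once (QR) and each genetic predictor is
projected against it (Frisch-Waugh-Lovell); the resulting t statistics and
two-sided P values are numerically identical to a full-design OLS.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


class CovariateProjector:
    """Pre-factorised covariate block for repeated single-predictor OLS.

    Parameters
    ----------
    covars : array (n, c) or None
        Covariate columns WITHOUT the intercept; an intercept is always
        included. Collinear columns are dropped via rank-revealing QR.
    """

    def __init__(self, covars: np.ndarray | None, n: int):
        if covars is None or (hasattr(covars, "size") and covars.size == 0):
            X = np.ones((n, 1))
        else:
            covars = np.asarray(covars, dtype=float)
            X = np.column_stack([np.ones(n), covars])
        q, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        keep = diag > max(diag.max(), 1.0) * 1e-10
        self.Q = q[:, keep]
        self.rank = int(keep.sum())
        self.n = n

    def residualize(self, v: np.ndarray) -> np.ndarray:
        """Project out the covariate block (v may be (n,) or (n, k))."""
        return v - self.Q @ (self.Q.T @ v)


def marginal_ols(
    y_res: np.ndarray, X_res: np.ndarray, df_resid: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS slope tests of covariate-residualised predictors against y.

    Parameters
    ----------
    y_res : (n,) covariate-residualised trait.
    X_res : (n, k) covariate-residualised predictor columns.
    df_resid : residual degrees of freedom, n - rank(covariates) - 1.

    Returns
    -------
    beta, se, p : arrays of length k. Degenerate columns (zero residual
    variance, i.e. predictor collinear with the covariates or constant)
    yield beta = 0, se = nan, p = 1.
    """
    X_res = np.atleast_2d(np.asarray(X_res, dtype=float))
    if X_res.shape[0] != y_res.shape[0]:
        X_res = X_res.T
    sxx = np.einsum("ij,ij->j", X_res, X_res)
    sxy = X_res.T @ y_res
    syy = float(y_res @ y_res)
    ok = sxx > 1e-12
    beta = np.zeros(X_res.shape[1])
    se = np.full(X_res.shape[1], np.nan)
    p = np.ones(X_res.shape[1])
    if df_resid <= 0:
        return beta, se, p
    beta[ok] = sxy[ok] / sxx[ok]
    rss = syy - beta[ok] ** 2 * sxx[ok]
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / df_resid
    se[ok] = np.sqrt(sigma2 / sxx[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se[ok] > 0, beta[ok] / se[ok], np.inf)
    p[ok] = 2.0 * stats.t.sf(np.abs(t), df_resid)
    # guard: P of 0 is rounded up to the smallest positive float
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return beta, se, p


def single_fit(
    y: np.ndarray, x: np.ndarray, covars: np.ndarray | None
) -> tuple[float, float, float, int]:
    """One complete-case OLS of y on x + covariates.

    Missing values in ``x`` are encoded as negative; rows containing them
    are dropped. Returns (beta, se, p, n_used).
    """
    x = np.asarray(x, dtype=float)
    mask = x >= 0
    n_used = int(mask.sum())
    if n_used < 3:
        return 0.0, float("nan"), 1.0, n_used
    yv = np.asarray(y, dtype=float)[mask]
    cv = None if covars is None else np.asarray(covars, dtype=float)[mask]
    proj = CovariateProjector(cv, n_used)
    beta, se, p = marginal_ols(
        proj.residualize(yv), proj.residualize(x[mask])[:, None], n_used - proj.rank - 1
    )
    return float(beta[0]), float(se[0]), float(p[0]), n_used


def adjust_trait(
    y: np.ndarray, covars: np.ndarray | None
) -> np.ndarray:
    """Residuals of the trait after regressing out the covariate block."""
    y = np.asarray(y, dtype=float)
    proj = CovariateProjector(covars, y.shape[0])
    return proj.residualize(y)
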