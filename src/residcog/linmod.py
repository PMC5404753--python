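"""Exact closed-form OLS helpers used by the association scans.

Every association in the pipeline is a linear model of the form
``y ~ 1 + covariates + x`` where only the coefficient of ``x`` is of
interest.  By the Frisch–Waugh–Lovell theorem that coefficient, its
standard error and its t-based p-value can be obtained by residualising
both ``x`` and ``y`` on the covariate block and running a simple
regression on the residuals with the full model's degrees of freedom.
This lets a whole scan (many ``x`` columns, or many permuted ``y``
columns) run as a handful of matrix products while remaining exactly
equal to the per-column OLS fit.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["covariate_basis", "residualize", "partial_regression", "partial_regression_many_y"]


def covariate_basis(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Orthonormal basis Q of the span of [intercept, covariates]."""
    if covariates is None or covariates.size == 0:
        Z = np.ones((n, 1))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        Z = np.column_stack([np.ones(n), C])
    Q, R = np.linalg.qr(Z)
    # drop numerically null columns so rank deficiency does not break df
    keep = np.abs(np.diag(R)) > 1e-10 * max(abs(np.diag(R)).max(), 1.0)
    return Q[:, keep]


def residualize(M: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Project columns of ``M`` off the orthonormal basis ``Q``."""
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        return M - Q @ (Q.T @ M)
    return M - Q @ (Q.T @ M)


def partial_regression(
    X: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column OLS of ``y`` on [1, covariates, X[:, j]].

    Returns (beta, se, p) arrays over the columns of ``X``.  p-values come
    from the t distribution with ``n - k - 2`` degrees of freedom, where k
    is the number of covariate columns (matching the full-model df).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    one_d = X.ndim == 1
    if one_d:
        X = X[:, None]
    n = y.shape[0]
    Q = covariate_basis(covariates, n)
    df = n - Q.shape[1] - 1
    if df <= 0:
        raise ValueError(f"not enough observations for the model (df={df})")
    Xr = residualize(X, Q)
    yr = residualize(y, Q)
    sxx = np.einsum("ij,ij->j", Xr, Xr)
    if np.any(sxx <= 1e-12 * n):
        raise ValueError("zero variance predictor")
    sxy = Xr.T @ yr
    syy = float(yr @ yr)
    beta = sxy / sxx
    rss = np.maximum(syy - beta * sxy, 0.0)
    se = np.sqrt(rss / df / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    se = np.maximum(se, np.finfo(float).tiny)  # exact fits: se is 0 to precision
    if one_d:
        return beta[0], se[0], p[0]
    return beta, se, p


def partial_regression_many_y(
    X: np.ndarray, Y: np.ndarray, covariates: np.ndarray | None = None
) -> np.ndarray:
    """p-values of the X-term for every (X column, Y column) pair.

    Used by the permutation machinery: ``X`` holds a region's CpGs and
    ``Y`` holds B permuted trait vectors.  Returns an (n_x, n_y) array of
    two-sided t p-values identical to refitting the full OLS per pair.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    Q = covariate_basis(covariates, n)
    df = n - Q.shape[1] - 1
    if df <= 0:
        raise ValueError(f"not enough observations for the model (df={df})")
    Xr = residualize(X, Q)
    Yr = residualize(Y, Q)
    sxx = np.einsum("ij,ij->j", Xr, Xr)
    if np.any(sxx <= 1e-12 * n):
        raise ValueError("zero variance predictor")
    syy = np.einsum("ij,ij->j", Yr, Yr)
    cross = Xr.T @ Yr  # (n_x, n_y)
    denom = sxx[:, None] * syy[None, :] - cross**2
    denom = np.maximum(denom, 1e-300)
    t = cross * np.sqrt(df / denom)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.clip(p, np.finfo(float).tiny, 1.0)
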