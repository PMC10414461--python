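"""Gaussian GEE with exchangeable working correlation (in-house solver).

Marginal model for repeated hospital-year observations:

    E[ERR_it] = x_it' beta,   Corr(ERR_it, ERR_is) = alpha  (t != s)

estimated by iterating (i) the working-correlation-weighted estimating
equations for beta — for the Gaussian/identity case an exact generalized
least-squares solve using the closed-form exchangeable inverse — and
(ii) moment re-estimation of the scale and of alpha from within-cluster
cross-products of Pearson residuals, until ``max |d beta| < tol``.

Moment conventions (bias-corrected denominators, p = number of
coefficients, N = rows, P = within-cluster pairs):

    scale = sum r^2 / (N - p)
    alpha = [ sum_i sum_{t<s} r_it r_is / scale ] / (P - p)

Standard errors are cluster-robust (sandwich): with B = sum X_i' R^-1 X_i
and M = sum (X_i' R^-1 r_i)(X_i' R^-1 r_i)', cov(beta) = B^-1 M B^-1 —
consistent even when the exchangeable working structure is wrong.
Clusters of size 1 contribute to the scale only; when every cluster has
size 1 the fit is exactly OLS with HC0-type robust covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GEEFit", "fit_gee", "wald_inference", "ADJUSTED", "UNADJUSTED"]

ADJUSTED = ["li", "pct_black", "pct_poverty", "pct_private", "pct_hispanic"]
UNADJUSTED = ["li"]


@dataclass
class GEEFit:
    """Fitted GEE: coefficients, sandwich SEs and the working correlation."""

    names: list
    beta: np.ndarray
    cov: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    alpha: float
    scale: float
    n_clusters: int
    n_obs: int
    converged: bool
    n_iter: int

    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.names)

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                name: {
                    "beta": float(b),
                    "se": float(s),
                    "z": float(z),
                    "p": float(p),
                }
                for name, b, s, z, p in zip(self.names, self.beta, self.se, self.z, self.p)
            },
            "alpha": float(self.alpha),
            "scale": float(self.scale),
            "n_clusters": self.n_clusters,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def _solve_exchangeable(block: np.ndarray, alpha: float) -> np.ndarray:
    """R^-1 @ block for the n x n exchangeable correlation, in O(n)."""
    n = block.shape[0]
    if n == 1 or alpha == 0.0:
        return block if alpha == 0.0 else block.copy()
    c = alpha / ((1.0 - alpha) * (1.0 + alpha * (n - 1)))
    return block / (1.0 - alpha) - c * block.sum(axis=0, keepdims=True)


def fit_gee(
    panel: pd.DataFrame,
    covariates=ADJUSTED,
    cluster: str = "hospital_id",
    outcome: str = "err",
    tol: float = 1e-8,
    max_iter: int = 100,
    fixed_alpha: float | None = None,
) -> GEEFit:
    """Fit the exchangeable Gaussian GEE on a panel DataFrame.

    ``covariates`` selects the regressors after the intercept (use
    :data:`UNADJUSTED` for the LI-only model).  ``fixed_alpha`` freezes the
    working correlation (0 gives working independence, i.e. pooled OLS
    coefficients).  Rows with missing outcome or covariates are dropped
    listwise.  Non-convergence is flagged, never silent.
    """
    cols = [outcome, cluster] + list(covariates)
    data = panel[cols].dropna()
    n_drop = len(panel) - len(data)
    if n_drop:
        import logging

        logging.getLogger(__name__).warning("fit_gee: dropped %d incomplete rows", n_drop)
    y = data[outcome].to_numpy(float)
    X = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(float) for c in covariates])
    names = ["intercept"] + list(covariates)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    codes, _ = pd.factorize(data[cluster], sort=False)
    order = np.argsort(codes, kind="stable")
    Xs, ys, cs = X[order], y[order], codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(cs) != 0])
    bounds = list(zip(starts, np.r_[starts[1:], n]))
    if len(bounds) < 2:
        raise ValueError("need at least 2 clusters")
    n_pairs = sum(0.5 * (b - a) * (b - a - 1) for a, b in bounds)

    beta = np.linalg.lstsq(Xs, ys, rcond=None)[0]
    alpha = 0.0 if fixed_alpha is None else float(fixed_alpha)
    scale = np.nan
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        B = np.zeros((p, p))
        rhs = np.zeros(p)
        for a, b in bounds:
            Xi, yi = Xs[a:b], ys[a:b]
            Vi = _solve_exchangeable(Xi, alpha)
            B += Xi.T @ Vi
            rhs += Vi.T @ yi
        beta_new = np.linalg.solve(B, rhs)
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        resid = ys - Xs @ beta
        scale = float(resid @ resid) / (n - p)
        if fixed_alpha is None:
            pair_sum = sum(
                0.5 * (resid[a:b].sum() ** 2 - resid[a:b] @ resid[a:b]) for a, b in bounds
            )
            # degenerate cases (noiseless fit, too few pairs) fall back to 0
            if scale > 0 and n_pairs > p:
                alpha_new = (pair_sum / scale) / (n_pairs - p)
            else:
                alpha_new = 0.0
            delta = max(delta, abs(alpha_new - alpha))
            alpha = alpha_new
        if delta < tol:
            converged = True
            break

    B = np.zeros((p, p))
    M = np.zeros((p, p))
    resid = ys - Xs @ beta
    for a, b in bounds:
        Xi, ri = Xs[a:b], resid[a:b]
        Vi = _solve_exchangeable(Xi, alpha)
        B += Xi.T @ Vi
        g = Vi.T @ ri
        M += np.outer(g, g)
    Binv = np.linalg.inv(B)
    cov = Binv @ M @ Binv
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return GEEFit(
        names=names,
        beta=beta,
        cov=cov,
        se=se,
        z=z,
        p=pvals,
        alpha=float(alpha),
        scale=scale,
        n_clusters=len(bounds),
        n_obs=n,
        converged=converged,
        n_iter=it,
    )


def wald_inference(fit: GEEFit, level: float = 0.95) -> pd.DataFrame:
    """Per-coefficient z, two-sided normal p and Wald confidence interval."""
    zq = stats.norm.ppf(0.5 + level / 2.0)
    return pd.DataFrame(
        {
            "coefficient": fit.names,
            "beta": fit.beta,
            "se": fit.se,
            "z": fit.z,
            "p": fit.p,
            "ci_low": fit.beta - zq * fit.se,
            "ci_high": fit.beta + zq * fit.se,
        }
    )
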