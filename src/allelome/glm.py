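"""Negative-binomial GLM core: size factors, dispersion, IRLS fit, Wald/LRT.

The NB2 model with log link: y ~ NB(mu, alpha) with Var(y) = mu + alpha*mu^2,
log(mu) = X beta + offset. Fitting is iteratively reweighted least squares
with working weights w = mu / (1 + alpha*mu); the observed-information
covariance (X' W X)^{-1} gives Wald statistics. Dispersion is estimated
per gene by method of moments on normalised counts (floored), which keeps
the per-gene fits independent and fast.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

DISPERSION_FLOOR = 1e-4
LN2 = float(np.log(2.0))


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (one per sample column).

    Uses genes with all-positive counts as the reference set; falls back to
    library-size scaling if none exist.
    """
    mat = np.asarray(counts, dtype=float)
    positive = (mat > 0).all(axis=1)
    if positive.sum() == 0:
        libs = mat.sum(axis=0)
        sf = libs / np.exp(np.mean(np.log(np.maximum(libs, 1.0))))
        return sf
    ref = mat[positive]
    log_geo = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = np.log(ref) - log_geo
    return np.exp(np.median(ratios, axis=0))


def mom_dispersion(
    y: np.ndarray, sf: np.ndarray, groups: np.ndarray, floor: float = DISPERSION_FLOOR
) -> float:
    """Method-of-moments NB dispersion pooled over replicate groups.

    ``groups`` labels replicate sets sharing a mean; the excess of the
    normalised-count variance over the Poisson expectation, relative to the
    squared mean, is averaged across groups (weighted by group size).
    """
    z = y / sf
    num = 0.0
    den = 0.0
    for g in np.unique(groups):
        zi = z[groups == g]
        if len(zi) < 2:
            continue
        m = zi.mean()
        if m <= 0:
            continue
        v = zi.var(ddof=1)
        # subtract the mean Poisson variance on the normalised scale
        pois = m * np.mean(1.0 / sf[groups == g])
        num += (len(zi) - 1) * max(v - pois, 0.0) / (m * m)
        den += len(zi) - 1
    alpha = num / den if den > 0 else floor
    return max(alpha, floor)


@dataclasses.dataclass
class NBFit:
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    alpha: float
    mu: np.ndarray
    converged: bool

    def wald(self, j: int) -> tuple[float, float]:
        """Wald z and two-sided p for coefficient j."""
        se = float(np.sqrt(self.cov[j, j]))
        z = float(self.beta[j]) / se if se > 0 else 0.0
        return z, float(2.0 * stats.norm.sf(abs(z)))


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    if alpha <= 0:
        return float(np.sum(stats.poisson.logpmf(y, mu)))
    r = 1.0 / alpha
    return float(np.sum(stats.nbinom.logpmf(y, r, r / (r + mu))))


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    alpha: float,
    offset: np.ndarray | None = None,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> NBFit:
    """Fit an NB2 GLM with log link by IRLS.

    ``offset`` carries log size factors. Raises on rank-deficient designs.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design matrix")
    if offset is None:
        offset = np.zeros(n)
    if not np.any(y > 0):
        raise ValueError("need at least one positive count")
    # start from the mean model
    mu = np.maximum(y, 0.5)
    eta = np.log(mu) - offset
    beta = np.linalg.lstsq(X, eta, rcond=None)[0]
    converged = False
    for _ in range(maxiter):
        eta = X @ beta + offset
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        xtw = X.T * w
        try:
            beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            break
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break
    eta = np.clip(X @ beta + offset, -30, 30)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    xtwx = (X.T * w) @ X
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return NBFit(beta=beta, cov=cov, loglik=nb_loglik(y, mu, alpha), alpha=alpha,
                 mu=mu, converged=converged)


def lrt(full: NBFit, reduced: NBFit, df: int = 1) -> float:
    """Likelihood-ratio p-value comparing nested NB fits at equal dispersion."""
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    return float(stats.chi2.sf(stat, df))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        return p
    finite = np.isfinite(p)
    out = np.full(n, np.nan)
    pf = p[finite]
    m = pf.size
    if m:
        order = np.argsort(pf, kind="mergesort")
        ranked = pf[order] * m / np.arange(1, m + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        vals = np.empty(m)
        vals[order] = np.minimum(q, 1.0)
        out[finite] = vals
    return out
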