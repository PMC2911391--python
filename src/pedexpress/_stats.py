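"""Shared statistical primitives.

Low-level routines used across modules: Benjamini-Hochberg q-values,
bivariate normal rectangle probabilities, and a quasi-Monte-Carlo
integrator for multivariate normal rectangle probabilities (Genz's
separation-of-variables construction) used by the liability models.
"""

from __future__ import annotations

import numpy as np
from scipy import special
from scipy.stats import qmc
from statsmodels.stats.multitest import multipletests

_TINY = 1e-300


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone adjusted p-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def norm_cdf(x):
    return special.ndtr(x)


def norm_ppf(x):
    return special.ndtri(x)


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Evaluated by Gauss-Legendre quadrature of the identity
    d/dr Phi2(h, k; r) = phi2(h, k; r), integrating from r = 0 where the
    CDF factorizes.  Accurate to ~1e-12 for |rho| <= 0.99.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    if np.isinf(h) or np.isinf(k):
        if h == -np.inf or k == -np.inf:
            return 0.0
        if h == np.inf:
            return float(special.ndtr(k))
        if k == np.inf:
            return float(special.ndtr(h))
    if rho == 1.0:
        return float(special.ndtr(min(h, k)))
    if rho == -1.0:
        return float(max(0.0, special.ndtr(h) + special.ndtr(k) - 1.0))
    nodes, weights = np.polynomial.legendre.leggauss(96)
    r = 0.5 * rho * (nodes + 1.0)
    w = 0.5 * rho * weights
    om = 1.0 - r * r
    dens = np.exp(-(h * h - 2.0 * r * h * k + k * k) / (2.0 * om)) / (
        2.0 * np.pi * np.sqrt(om)
    )
    val = special.ndtr(h) * special.ndtr(k) + float(np.sum(w * dens))
    return float(min(1.0, max(0.0, val)))


def sobol_points(dim: int, n_points: int, seed: int) -> np.ndarray:
    """Scrambled Sobol points in (0,1)^dim with a fixed seed.

    The scramble seed is fixed per integrator instance so repeated
    likelihood evaluations see identical points (smooth, optimizable
    objective).
    """
    if dim == 0:
        return np.empty((n_points, 0))
    eng = qmc.Sobol(d=dim, scramble=True, seed=seed)
    u = eng.random(n_points)
    # keep strictly inside (0,1) for the inverse-CDF step
    return np.clip(u, 1e-12, 1.0 - 1e-12)


def mvn_rect_prob(
    lower: np.ndarray,
    upper: np.ndarray,
    chol: np.ndarray,
    points: np.ndarray,
) -> np.ndarray:
    """Rectangle probabilities P(lower < Z < upper), Z ~ N(0, L L').

    Genz sequential-conditioning estimator, vectorized over a batch of
    rectangles sharing one Cholesky factor ``chol`` (lower triangular).

    Parameters
    ----------
    lower, upper : (B, d) arrays, entries may be +-inf.
    chol : (d, d) lower-triangular Cholesky factor of the covariance.
    points : (n, d-1) quasi-random points in (0,1); ignored columns for d=1.

    Returns
    -------
    (B,) array of probability estimates.
    """
    lower = np.atleast_2d(np.asarray(lower, dtype=float))
    upper = np.atleast_2d(np.asarray(upper, dtype=float))
    B, d = lower.shape
    L = np.asarray(chol, dtype=float)
    if d == 1:
        s = L[0, 0]
        return np.maximum(
            special.ndtr(upper[:, 0] / s) - special.ndtr(lower[:, 0] / s), _TINY
        )
    n = points.shape[0]
    prob = np.ones((B, n))
    y = np.zeros((B, n, d - 1))
    for j in range(d):
        mu = y[:, :, :j] @ L[j, :j] if j else np.zeros((B, n))
        at = (lower[:, j, None] - mu) / L[j, j]
        bt = (upper[:, j, None] - mu) / L[j, j]
        Fa = special.ndtr(at)
        Fb = special.ndtr(bt)
        width = np.clip(Fb - Fa, 0.0, 1.0)
        prob *= width
        if j < d - 1:
            u = points[None, :, j]
            inner = np.clip(Fa + u * width, 1e-13, 1.0 - 1e-13)
            y[:, :, j] = special.ndtri(inner)
    return np.maximum(prob.mean(axis=1), _TINY)


def mvn_logpdf_chol(resid: np.ndarray, chol: np.ndarray) -> np.ndarray:
    """Log density of N(0, L L') at a batch of residual vectors (B, d)."""
    from scipy.linalg import solve_triangular

    resid = np.atleast_2d(resid)
    d = resid.shape[1]
    z = solve_triangular(chol, resid.T, lower=True)
    quad = np.sum(z * z, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + quad)
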