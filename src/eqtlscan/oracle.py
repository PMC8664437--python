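"""Slow, transparent per-marker regression oracle.

Computes the same one-df LOD score as the fast matrix-product scan, but
the obvious way: for every trait/marker pair, fit the null model (trait on
intercept plus covariates) and the alternative (plus the marker) by least
squares and take LOD = (n/2) log10(RSS0/RSS1).  This is the definition the
fast path must reproduce, so it serves as the correctness reference in
tests; it is deliberately an explicit double loop over ordinary
regressions and shares no code with the scan engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

# mirror the fast path's r^2 ceiling so the two stay comparable at a perfect fit
R2_CLAMP = 1.0 - 1e-12

#: brute_scan refuses problems with more trait x marker pairs than this
BRUTE_GUARD = 10**6


@dataclass
class OlsFit:
    design: np.ndarray
    coefficients: np.ndarray
    residuals: np.ndarray
    rss: float
    sigma2: float
    n_obs: int


@dataclass
class NestedLod:
    rss0: float
    rss1: float
    lod: float


def fit_ols(y: np.ndarray, X: np.ndarray) -> OlsFit:
    """Least squares y ~ X via QR; errors on rank-deficient X."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.shape[0] != X.shape[0]:
        raise ValueError("y and X have different numbers of rows")
    q, r = scipy.linalg.qr(X, mode="economic")
    diag = np.abs(np.diag(r))
    if diag.min() <= diag.max() * max(X.shape) * np.finfo(float).eps:
        raise ValueError("design matrix is rank deficient")
    coef = scipy.linalg.solve_triangular(r, q.T @ y)
    resid = y - X @ coef
    rss = float(resid @ resid)
    n = y.shape[0]
    return OlsFit(X, coef, resid, rss, rss / n, n)


def lod_ols(
    y: np.ndarray,
    g: np.ndarray,
    Z: np.ndarray | None = None,
    r2_clamp: float = R2_CLAMP,
) -> NestedLod:
    """One-df LOD for a single trait/marker pair from nested regressions.

    Z, when given, must include the intercept; otherwise the null design
    is the intercept alone.  A marker collinear with Z raises.
    """
    y = np.asarray(y, dtype=float).ravel()
    g = np.asarray(g, dtype=float).ravel()
    n = y.shape[0]
    if Z is None:
        Z = np.ones((n, 1))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    null = fit_ols(y, Z)
    try:
        full = fit_ols(y, np.column_stack([Z, g]))
    except ValueError as exc:
        raise ValueError("marker is collinear with the covariates") from exc
    rss0, rss1 = null.rss, full.rss
    if rss0 <= 0.0:
        # constant-in-covariate-space trait: no variance left to explain
        return NestedLod(rss0, rss1, 0.0)
    # numerical nesting guard plus the perfect-fit clamp (same ceiling as
    # the fast path's r^2 clamp: rss1/rss0 = 1 - r^2 >= 1 - r2_clamp)
    rss1 = min(max(rss1, rss0 * (1.0 - r2_clamp)), rss0)
    lod = (n / 2.0) * np.log10(rss0 / rss1)
    return NestedLod(rss0, rss1, float(lod))


def brute_scan(
    traits: np.ndarray,
    geno: np.ndarray,
    Z: np.ndarray | None = None,
) -> np.ndarray:
    """Full traits x markers LOD matrix by looping lod_ols over every pair.

    Accepts plain arrays (strains x traits, strains x markers) or the
    package's TraitMatrix / GenotypeMatrix containers.  Guarded to small
    problems (m * p <= 10^6); use the scan engine for anything larger.
    """
    Y = np.asarray(getattr(traits, "values", traits), dtype=float)
    G = np.asarray(getattr(geno, "dosage", geno), dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if G.ndim == 1:
        G = G[:, None]
    m, p = Y.shape[1], G.shape[1]
    if m * p > BRUTE_GUARD:
        raise ValueError(
            f"brute_scan guard exceeded ({m} x {p} pairs); use eqtlscan.scan.GenomeScan"
        )
    out = np.empty((m, p))
    for i in range(m):
        for j in range(p):
            out[i, j] = lod_ols(Y[:, i], G[:, j], Z).lod
    return out
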