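"""Bulk eQTL genome scan via standardized matrix products.

For a two-genotype-class cross (backcross or recombinant inbred panel) the
one-degree-of-freedom LOD score between trait i and marker j reduces to a
function of their Pearson correlation:

    LOD_ij = (n/2) log10(RSS0_i / RSS1_ij) = -(n/2) log10(1 - r_ij^2)

so the whole traits x markers LOD matrix is an element-wise transform of
R = (1/n) Y*' G*, where Y* and G* are the column-standardized trait and
genotype matrices.  Covariates Z (including an intercept) are handled by
projecting both Y and G onto the orthogonal complement of the covariate
space before standardizing; the projector P = I - Z(Z'Z)^-1 Z' is never
materialized — residuals come from a QR least-squares solve.

The scan runs in three steps (standardize, multiply, element-wise LOD) and
can either return the full LOD matrix or reduce each trait to its best
marker (max mode), which keeps the output small when m is huge.  Traits
are processed in chunks so the m x p matrix is never held in memory in max
mode.  All arithmetic runs in a selectable precision (float32 or float64).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Literal

import numpy as np
import pandas as pd
import scipy.linalg

from .io import CovariateMatrix, GenotypeMatrix, TraitMatrix

logger = logging.getLogger("eqtlscan")

#: Pluggable dense cross-product backends: f(A, B) -> A'B.  Only the CPU
#: backend ships; an accelerator can register here without touching the scan.
BACKENDS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "cpu": lambda a, b: a.T @ b,
}

_DTYPES = {"single": np.float32, "double": np.float64}


@dataclass
class ScanConfig:
    """Scan settings.

    precision: 'single' (float32) or 'double' (float64) arithmetic.
    output_mode: 'full' (m x p LOD matrix) or 'max' (per-trait peak).
    maf_threshold: markers with minor allele frequency below this are
        dropped before scanning (0 keeps everything).
    lod_report_threshold: peak filter used by plotting/reporting only.
    trait_chunk: number of trait columns per correlation block.
    r2_clamp: r^2 ceiling before the log, keeping LOD finite when a trait
        duplicates a marker (LOD caps at 6n with the default).
    """

    precision: Literal["single", "double"] = "double"
    output_mode: Literal["full", "max"] = "max"
    maf_threshold: float = 0.05
    lod_report_threshold: float = 0.0
    trait_chunk: int = 10_000
    r2_clamp: float = 1.0 - 1e-12
    backend: str = "cpu"

    def __post_init__(self) -> None:
        if self.precision not in _DTYPES:
            raise ValueError("precision must be 'single' or 'double'")
        if self.output_mode not in ("full", "max"):
            raise ValueError("output_mode must be 'full' or 'max'")
        if not 0.0 <= self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must be in [0, 0.5]")
        if self.lod_report_threshold < 0:
            raise ValueError("lod_report_threshold must be >= 0")
        if int(self.trait_chunk) < 1:
            raise ValueError("trait_chunk must be a positive integer")
        self.trait_chunk = int(self.trait_chunk)
        if not 0.0 < self.r2_clamp < 1.0:
            raise ValueError("r2_clamp must be in (0, 1)")
        if self.backend not in BACKENDS:
            raise ValueError(f"unknown backend {self.backend!r}")

    @property
    def dtype(self) -> type:
        return _DTYPES[self.precision]


@dataclass
class StandardizedMatrix:
    """Column-standardized matrix: non-constant columns have mean 0 and
    population variance 1; constant columns are zeroed and masked."""

    values: np.ndarray
    n_obs: int
    constant_mask: np.ndarray


@dataclass
class CorrelationBlock:
    """Pearson correlations, traits x markers; masked columns give 0."""

    r: np.ndarray
    n_obs: int


@dataclass
class LodResult:
    """Outcome of a scan: the full LOD matrix or a per-trait peak table."""

    mode: Literal["full", "max"]
    n_obs: int
    config: ScanConfig
    trait_ids: list[str]
    marker_ids: list[str]
    lod: np.ndarray | None = None            # full mode: m x p
    peaks: pd.DataFrame | None = None        # max mode (and derivable in full)
    kept_marker_index: np.ndarray | None = None  # original indices of scanned markers


class ProjectionContext:
    """Residual-maker for a covariate block Z (intercept first).

    Holds the thin QR factor of Z; applying the context to a matrix M
    returns PM = M - Q(Q'M), the residuals of M after regressing on Z.
    Idempotent, and annihilates anything in the column space of Z.
    """

    def __init__(self, Z: CovariateMatrix | np.ndarray, dtype=np.float64):
        values = Z.values if isinstance(Z, CovariateMatrix) else np.asarray(Z)
        names = Z.names if isinstance(Z, CovariateMatrix) else None
        values = np.asarray(values, dtype=dtype)
        if values.ndim != 2:
            raise ValueError("Z must be 2-D")
        q, r, piv = scipy.linalg.qr(values, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(values.shape) * np.finfo(dtype).eps
        deficient = np.flatnonzero(diag <= tol)
        if deficient.size:
            col = int(piv[deficient[0]])
            name = names[col] if names else f"column {col}"
            raise ValueError(f"covariate matrix is rank deficient: {name} is collinear")
        self.q = q
        self.n_obs = values.shape[0]

    def apply(self, M: np.ndarray) -> np.ndarray:
        M = np.asarray(M, dtype=self.q.dtype)
        if M.shape[0] != self.n_obs:
            raise ValueError("row count of M does not match covariates")
        return M - self.q @ (self.q.T @ M)


def residualize(M: np.ndarray, ctx: ProjectionContext) -> np.ndarray:
    """Project M onto the orthogonal complement of the covariate space."""
    return ctx.apply(M)


def standardize_columns(M: np.ndarray, dtype=None) -> StandardizedMatrix:
    """Center each column and scale to population variance 1.

    Scaling is by the population (1/n) standard deviation so that the
    subsequent cross-product divided by n is exactly Pearson correlation.
    Zero-variance columns are set to 0 and flagged in ``constant_mask``.
    """
    X = np.asarray(M)
    if dtype is not None:
        X = X.astype(dtype, copy=False)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations to standardize")
    if np.isnan(X).any():
        raise ValueError(
            "input contains missing values; run drop_incomplete (or impute) first"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    scale = np.sqrt(np.mean(Xc * Xc, axis=0))
    # a column is 'constant' when its spread is at rounding level for its magnitude
    tol = 10 * np.finfo(X.dtype).eps * np.maximum(np.abs(mean), 1e-30)
    const = scale <= tol
    safe = np.where(const, 1.0, scale).astype(X.dtype)
    Z = Xc / safe
    if const.any():
        Z[:, const] = 0.0
        logger.info("standardize_columns: %d constant column(s) masked", int(const.sum()))
    return StandardizedMatrix(Z, n, const)


def correlation_scan(
    Ys: StandardizedMatrix, Gs: StandardizedMatrix, backend: str = "cpu"
) -> CorrelationBlock:
    """Bulk Pearson correlation R = (1/n) Y*' G* by matrix multiplication."""
    if Ys.n_obs != Gs.n_obs or Ys.values.shape[0] != Gs.values.shape[0]:
        raise ValueError("trait and genotype matrices have different row counts")
    n = Ys.n_obs
    r = BACKENDS[backend](Ys.values, Gs.values) / Ys.values.dtype.type(n)
    return CorrelationBlock(r, n)


def lod_from_r2(r2, n: int, r2_clamp: float = 1.0 - 1e-12):
    """One-df LOD score from squared correlation: -(n/2) log10(1 - r^2).

    r^2 is clamped at ``r2_clamp`` so a perfect fit stays finite.
    Accepts scalars or arrays.
    """
    if n < 3:
        raise ValueError("n must be at least 3")
    r2 = np.asarray(r2)
    if (r2 < 0).any() or (r2 > 1 + 1e-8).any():
        raise ValueError("r2 must lie in [0, 1]")
    dt = r2.dtype if np.issubdtype(r2.dtype, np.floating) else np.dtype(np.float64)
    clipped = np.minimum(r2.astype(dt), dt.type(r2_clamp))
    # log1p keeps accuracy for r^2 near 0 (LOD ~ n r^2 / (2 ln 10))
    out = np.log1p(-clipped) * dt.type(-(n / 2.0) / np.log(10.0))
    out = np.asarray(out, dtype=dt)
    return out if out.ndim else float(out)


def maf_filter(
    geno: GenotypeMatrix, threshold: float
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Drop markers with minor allele frequency below ``threshold``.

    Allele frequency is the column mean dosage f; a marker is kept iff
    min(f, 1-f) >= threshold.  Returns the filtered matrix and the
    original column indices of the kept markers.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must be in [0, 0.5]")
    if np.isnan(geno.dosage).any():
        raise ValueError("genotypes contain missing values; resolve before MAF filter")
    if threshold == 0.0:
        kept = np.arange(geno.n_markers)
        return geno, kept
    f = geno.dosage.mean(axis=0)
    keep = np.minimum(f, 1.0 - f) >= threshold
    kept = np.flatnonzero(keep)
    if kept.size == 0:
        raise ValueError("no markers survive filter (MAF threshold too strict)")
    if kept.size < geno.n_markers:
        logger.info(
            "maf_filter: kept %d of %d markers at MAF >= %g",
            kept.size, geno.n_markers, threshold,
        )
    out = GenotypeMatrix(geno.dosage[:, kept], geno.strain_ids, geno.map.subset(kept))
    return out, kept


class GenomeScan:
    """Bulk one-df eQTL genome scan, scikit-learn style.

    Parameters mirror :class:`ScanConfig`.  After :meth:`fit`, results are
    in ``peaks_`` (max mode: one row per trait with the best marker and its
    LOD) or ``lod_`` (full mode: traits x markers matrix), plus
    ``n_obs_``, ``kept_marker_index_`` and ``result_``.

    Example
    -------
    >>> scanner = GenomeScan(output_mode="max", maf_threshold=0.05)
    >>> scanner.fit(geno, traits)                      # doctest: +SKIP
    >>> scanner.peaks_.head()                          # doctest: +SKIP
    """

    def __init__(
        self,
        precision: str = "double",
        output_mode: str = "max",
        maf_threshold: float = 0.05,
        lod_report_threshold: float = 0.0,
        trait_chunk: int = 10_000,
        r2_clamp: float = 1.0 - 1e-12,
        backend: str = "cpu",
    ):
        self.precision = precision
        self.output_mode = output_mode
        self.maf_threshold = maf_threshold
        self.lod_report_threshold = lod_report_threshold
        self.trait_chunk = trait_chunk
        self.r2_clamp = r2_clamp
        self.backend = backend

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "precision": self.precision,
            "output_mode": self.output_mode,
            "maf_threshold": self.maf_threshold,
            "lod_report_threshold": self.lod_report_threshold,
            "trait_chunk": self.trait_chunk,
            "r2_clamp": self.r2_clamp,
            "backend": self.backend,
        }

    def set_params(self, **params) -> "GenomeScan":
        valid = self.get_params()
        for k, v in params.items():
            if k not in valid:
                raise ValueError(f"invalid parameter {k!r} for GenomeScan")
            setattr(self, k, v)
        return self

    def _config(self) -> ScanConfig:
        return ScanConfig(
            precision=self.precision,
            output_mode=self.output_mode,
            maf_threshold=self.maf_threshold,
            lod_report_threshold=self.lod_report_threshold,
            trait_chunk=self.trait_chunk,
            r2_clamp=self.r2_clamp,
            backend=self.backend,
        )

    # -- the scan -----------------------------------------------------------
    def fit(
        self,
        geno: GenotypeMatrix,
        traits: TraitMatrix,
        covariates: CovariateMatrix | None = None,
    ) -> "GenomeScan":
        config = self._config()
        if geno.strain_ids != traits.strain_ids:
            raise ValueError(
                "genotype and trait strain ids differ; run align_strains first"
            )
        if covariates is not None and covariates.strain_ids != geno.strain_ids:
            raise ValueError("covariate strain ids differ; run align_strains first")
        n = geno.n_strains
        if n < 3:
            raise ValueError("need at least 3 strains")
        if np.isnan(traits.values).any():
            raise ValueError(
                "traits contain missing values; run drop_incomplete first"
            )
        if np.isnan(geno.dosage).any():
            raise ValueError("genotypes contain missing values; resolve before scanning")

        gkept, kept = maf_filter(geno, config.maf_threshold)
        dtype = config.dtype
        G = gkept.dosage.astype(dtype)
        Y = traits.values.astype(dtype)
        if covariates is not None:
            ctx = ProjectionContext(covariates, dtype=dtype)
            G = ctx.apply(G)
            Y = ctx.apply(Y)
        Gs = standardize_columns(G)
        m, p = Y.shape[1], G.shape[1]
        logger.info("scan: n=%d strains, m=%d traits, p=%d markers (%s precision)",
                    n, m, p, config.precision)

        half_n = n / 2.0
        clamp = dtype(config.r2_clamp)
        full = np.empty((m, p), dtype=dtype) if config.output_mode == "full" else None
        peak_idx = np.empty(m, dtype=np.int64)
        peak_lod = np.empty(m, dtype=dtype)
        for start in range(0, m, config.trait_chunk):
            sl = slice(start, min(start + config.trait_chunk, m))
            Ys = standardize_columns(Y[:, sl])
            block = correlation_scan(Ys, Gs, backend=config.backend)
            r2 = block.r * block.r
            np.minimum(r2, clamp, out=r2)
            lod = np.log1p(-r2)
            lod *= dtype(-half_n / np.log(10.0))
            if full is not None:
                full[sl, :] = lod
            # argmax ties resolve to the lowest marker index (first occurrence)
            idx = lod.argmax(axis=1)
            peak_idx[sl] = idx
            peak_lod[sl] = lod[np.arange(lod.shape[0]), idx]

        gm = gkept.map
        peaks = pd.DataFrame(
            {
                "trait_id": traits.trait_ids,
                "marker_id": gm.marker_ids[peak_idx],
                "chromosome": gm.chromosomes[peak_idx],
                "position_cM": gm.positions_cm[peak_idx],
                "lod": peak_lod.astype(np.float64),
            }
        )
        self.result_ = LodResult(
            mode=config.output_mode,
            n_obs=n,
            config=config,
            trait_ids=list(traits.trait_ids),
            marker_ids=list(gm.marker_ids),
            lod=full,
            peaks=peaks,
            kept_marker_index=kept,
        )
        self.lod_ = full
        self.peaks_ = peaks
        self.n_obs_ = n
        self.kept_marker_index_ = kept
        self.map_ = gm
        return self

    def fit_scan(self, geno, traits, covariates=None) -> LodResult:
        return self.fit(geno, traits, covariates).result_


def scan(
    geno: GenotypeMatrix,
    traits: TraitMatrix,
    covariates: CovariateMatrix | None = None,
    config: ScanConfig | None = None,
    **overrides,
) -> LodResult:
    """Functional wrapper around :class:`GenomeScan`."""
    config = replace(config, **overrides) if config is not None else ScanConfig(**overrides)
    scanner = GenomeScan(**{f: getattr(config, f) for f in (
        "precision", "output_mode", "maf_threshold", "lod_report_threshold",
        "trait_chunk", "r2_clamp", "backend")})
    return scanner.fit_scan(geno, traits, covariates)
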