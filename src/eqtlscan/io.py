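"""Reading and writing genotype, trait and covariate data.

Genotypes come as GeneNetwork-style ``.geno`` files: tab- or
whitespace-delimited text, one marker per row, with ``Chr``, ``Locus``,
``cM`` (and optionally ``Mb``) columns followed by one allele-code column
per strain.  Lines beginning with ``@`` (metadata) or ``#`` (comments) are
skipped.  Allele codes are mapped to dosages through a configurable code
map; the default suits a two-founder recombinant inbred panel such as the
BXD family (B -> 0, D -> 1, H -> 0.5, U -> missing).

Traits and covariates are plain delimited text with a header row of column
ids and a first column of strain ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("eqtlscan")

#: Default allele-code -> dosage map for a B x D recombinant inbred panel.
DEFAULT_CODE_MAP: dict[str, float] = {"B": 0.0, "D": 1.0, "H": 0.5, "U": np.nan}

_GENO_FIXED_COLS = ("Chr", "Locus", "cM")


@dataclass
class GeneticMap:
    """Marker positions on a genetic map.

    Markers are kept in file order; within a chromosome the cM positions
    must be non-decreasing.  ``positions_mb`` is ``None`` when the source
    file carries no physical positions.
    """

    marker_ids: np.ndarray
    chromosomes: np.ndarray
    positions_cm: np.ndarray
    positions_mb: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)
        if self.positions_mb is not None:
            self.positions_mb = np.asarray(self.positions_mb, dtype=float)
        ids, counts = np.unique(self.marker_ids, return_counts=True)
        if (counts > 1).any():
            dup = ids[counts > 1][0]
            raise ValueError(f"duplicate marker id: {dup!r}")
        if (self.positions_cm < 0).any():
            raise ValueError("cM positions must be non-negative")
        # positions must be non-decreasing within each chromosome, in file order
        for chrom in pd.unique(self.chromosomes):
            pos = self.positions_cm[self.chromosomes == chrom]
            if (np.diff(pos) < 0).any():
                raise ValueError(f"cM positions decrease within chromosome {chrom!r}")

    def __len__(self) -> int:
        return len(self.marker_ids)

    def subset(self, index: np.ndarray) -> "GeneticMap":
        return GeneticMap(
            self.marker_ids[index],
            self.chromosomes[index],
            self.positions_cm[index],
            None if self.positions_mb is None else self.positions_mb[index],
        )

    def to_frame(self) -> pd.DataFrame:
        d = {
            "marker_id": self.marker_ids,
            "chromosome": self.chromosomes,
            "position_cM": self.positions_cm,
        }
        if self.positions_mb is not None:
            d["position_Mb"] = self.positions_mb
        return pd.DataFrame(d)


@dataclass
class GenotypeMatrix:
    """Strains x markers dosage matrix tied to a :class:`GeneticMap`.

    Dosages lie in [0, 1]; missing genotypes are NaN and must be resolved
    before scanning.
    """

    dosage: np.ndarray
    strain_ids: list[str]
    map: GeneticMap

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.strain_ids = list(self.strain_ids)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (strains x markers)")
        if self.dosage.shape[0] != len(self.strain_ids):
            raise ValueError("row count does not match number of strain ids")
        if self.dosage.shape[1] != len(self.map):
            raise ValueError("column count does not match map length")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise ValueError("duplicate strain ids")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 1)
        if bad.any():
            raise ValueError("dosages must lie in [0, 1]")

    @property
    def n_strains(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def take_strains(self, rows: Sequence[int]) -> "GenotypeMatrix":
        rows = list(rows)
        return GenotypeMatrix(
            self.dosage[rows, :], [self.strain_ids[i] for i in rows], self.map
        )


@dataclass
class TraitMatrix:
    """Strains x traits expression matrix.

    ``cognate_position`` optionally records, per trait, the genomic
    position of the gene the transcript maps to (used by the eQTL-map
    plot); it is a DataFrame indexed by trait id with ``chromosome`` and a
    position column.
    """

    values: np.ndarray
    strain_ids: list[str]
    trait_ids: list[str]
    cognate_position: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.strain_ids = list(self.strain_ids)
        self.trait_ids = [str(t) for t in self.trait_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (strains x traits)")
        if self.values.shape != (len(self.strain_ids), len(self.trait_ids)):
            raise ValueError("values shape does not match strain/trait ids")
        if len(set(self.trait_ids)) != len(self.trait_ids):
            raise ValueError("duplicate trait ids")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise ValueError("duplicate strain ids")

    @property
    def n_strains(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def take_strains(self, rows: Sequence[int]) -> "TraitMatrix":
        rows = list(rows)
        return TraitMatrix(
            self.values[rows, :],
            [self.strain_ids[i] for i in rows],
            self.trait_ids,
            self.cognate_position,
        )

    def take_traits(self, cols: Sequence[int]) -> "TraitMatrix":
        cols = list(cols)
        ids = [self.trait_ids[i] for i in cols]
        cog = self.cognate_position
        if cog is not None:
            cog = cog.loc[[t for t in ids if t in cog.index]]
        return TraitMatrix(self.values[:, cols], self.strain_ids, ids, cog)


@dataclass
class CovariateMatrix:
    """Strains x covariates design block; first column is the intercept."""

    values: np.ndarray
    strain_ids: list[str]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.strain_ids = list(self.strain_ids)
        if not self.names:
            self.names = [f"cov{i}" for i in range(self.values.shape[1])]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if not np.all(self.values[:, 0] == 1.0):
            raise ValueError("first covariate column must be the intercept (all 1)")
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise ValueError("covariate matrix is rank deficient")

    def take_strains(self, rows: Sequence[int]) -> "CovariateMatrix":
        rows = list(rows)
        return CovariateMatrix(
            self.values[rows, :], [self.strain_ids[i] for i in rows], self.names
        )


# ---------------------------------------------------------------------------
# readers


def read_geno(
    path: str | Path,
    code_map: Mapping[str, float] | None = None,
    sep: str | None = None,
) -> tuple[GeneticMap, GenotypeMatrix]:
    """Read a GeneNetwork-style ``.geno`` file.

    Parameters
    ----------
    path:
        File with ``Chr  Locus  cM  [Mb]  strain...`` header; ``@``/``#``
        lines are metadata and skipped.
    code_map:
        Allele code -> dosage (NaN flags missing).  Defaults to
        :data:`DEFAULT_CODE_MAP`.
    sep:
        Field separator; ``None`` splits on any whitespace (handles both
        tab- and space-delimited files).
    """
    codes = dict(DEFAULT_CODE_MAP if code_map is None else code_map)
    path = Path(path)
    header: list[str] | None = None
    chroms: list[str] = []
    locus: list[str] = []
    cm: list[float] = []
    mb: list[float] = []
    rows: list[list[float]] = []
    has_mb = False
    n_strains = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("@") or line.startswith("#"):
                continue
            fields = line.split(sep) if sep else line.split()
            if header is None:
                header = fields
                if header[: len(_GENO_FIXED_COLS)] != list(_GENO_FIXED_COLS):
                    raise ValueError(
                        f"{path}:{lineno}: header must start with "
                        f"{' '.join(_GENO_FIXED_COLS)}, got {header[:4]}"
                    )
                has_mb = len(header) > 3 and header[3] == "Mb"
                n_strains = len(header) - (4 if has_mb else 3)
                if n_strains < 1:
                    raise ValueError(f"{path}: no strain columns in header")
                continue
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            chroms.append(fields[0])
            locus.append(fields[1])
            cm.append(float(fields[2]))
            off = 3
            if has_mb:
                mb.append(float(fields[3]))
                off = 4
            row = []
            for code in fields[off:]:
                if code not in codes:
                    raise ValueError(
                        f"{path}:{lineno}: unknown allele code {code!r}"
                    )
                row.append(codes[code])
            rows.append(row)
    if header is None or not rows:
        raise ValueError(f"{path}: no marker rows found")
    strain_ids = header[4 if has_mb else 3 :]
    gmap = GeneticMap(
        np.array(locus, dtype=object),
        np.array(chroms, dtype=object),
        np.array(cm, dtype=float),
        np.array(mb, dtype=float) if has_mb else None,
    )
    # markers are file rows; store strains x markers
    dosage = np.array(rows, dtype=float).T
    geno = GenotypeMatrix(dosage, strain_ids, gmap)
    logger.info(
        "read_geno: %d strains x %d markers from %s", geno.n_strains, geno.n_markers, path
    )
    return gmap, geno


def write_geno(geno: GenotypeMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a :class:`GenotypeMatrix` in the ``.geno`` dialect.

    Dosages 0 / 0.5 / 1 become B / H / D; NaN becomes U.  Round-trips
    exactly through :func:`read_geno` with the default code map.
    """
    gmap = geno.map
    has_mb = gmap.positions_mb is not None

    def code(x: float) -> str:
        if np.isnan(x):
            return "U"
        if x == 0.0:
            return "B"
        if x == 1.0:
            return "D"
        if x == 0.5:
            return "H"
        raise ValueError(f"dosage {x} has no allele code; only 0/0.5/1/NaN writable")

    with open(path, "w") as fh:
        fh.write("@type:riset\n")
        cols = ["Chr", "Locus", "cM"] + (["Mb"] if has_mb else []) + list(geno.strain_ids)
        fh.write(sep.join(cols) + "\n")
        for j in range(len(gmap)):
            fields = [str(gmap.chromosomes[j]), str(gmap.marker_ids[j]), f"{gmap.positions_cm[j]:g}"]
            if has_mb:
                fields.append(f"{gmap.positions_mb[j]:g}")
            fields.extend(code(x) for x in geno.dosage[:, j])
            fh.write(sep.join(fields) + "\n")


def _read_table(path: str | Path, sep: str | None, na_token: str) -> pd.DataFrame:
    raw = pd.read_csv(
        path,
        sep=sep,
        engine="python" if sep is None else "c",
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        stripped = raw[col].str.strip()
        missing = (stripped == na_token) | (stripped == "")
        num = pd.to_numeric(stripped.where(~missing), errors="coerce")
        bad = num.isna() & ~missing
        if bad.any():
            strain = raw.index[bad.to_numpy()][0]
            raise ValueError(
                f"{path}: non-numeric value {raw.loc[strain, col]!r} "
                f"at strain {strain!r}, column {col!r}"
            )
        values[col] = num
    return values


def read_traits(
    path: str | Path, sep: str | None = None, na_token: str = "NA"
) -> TraitMatrix:
    """Read a delimited trait table (header of trait ids, first column strain ids)."""
    df = _read_table(path, sep, na_token)
    tm = TraitMatrix(df.to_numpy(), [str(s) for s in df.index], list(df.columns))
    logger.info("read_traits: %d strains x %d traits from %s", tm.n_strains, tm.n_traits, path)
    return tm


def read_covariates(
    path: str | Path, sep: str | None = None, na_token: str = "NA"
) -> CovariateMatrix:
    """Read covariates and prepend the intercept column.

    The file must not itself contain a constant column (that would be
    collinear with the intercept and fails the rank check).
    """
    df = _read_table(path, sep, na_token)
    if df.isna().to_numpy().any():
        raise ValueError(f"{path}: covariates must be complete (no missing values)")
    vals = np.column_stack([np.ones(len(df)), df.to_numpy()])
    return CovariateMatrix(vals, [str(s) for s in df.index], ["intercept"] + list(df.columns))


# ---------------------------------------------------------------------------
# alignment and missing data


def align_strains(
    geno: GenotypeMatrix,
    traits: TraitMatrix,
    covariates: CovariateMatrix | None = None,
):
    """Restrict all inputs to their shared strains, in genotype-file order.

    Returns ``(geno, traits)`` or ``(geno, traits, covariates)`` with
    identical strain order.  Requires at least 3 shared strains.
    """
    shared = set(geno.strain_ids) & set(traits.strain_ids)
    if covariates is not None:
        shared &= set(covariates.strain_ids)
    order = [s for s in geno.strain_ids if s in shared]
    if len(order) < 3:
        raise ValueError(f"only {len(order)} shared strains; need at least 3")
    g = geno if order == geno.strain_ids else geno.take_strains(
        [geno.strain_ids.index(s) for s in order]
    )
    t = traits if order == traits.strain_ids else traits.take_strains(
        [traits.strain_ids.index(s) for s in order]
    )
    logger.info("align_strains: n = %d shared strains", len(order))
    if covariates is None:
        return g, t
    c = covariates if order == covariates.strain_ids else covariates.take_strains(
        [covariates.strain_ids.index(s) for s in order]
    )
    return g, t, c


def drop_incomplete(traits: TraitMatrix) -> TraitMatrix:
    """Remove traits with any missing value; missing data is resolved
    up front rather than imputed inside the scan."""
    complete = ~np.isnan(traits.values).any(axis=0)
    if not complete.any():
        raise ValueError("all traits have missing data; nothing left to scan")
    dropped = [t for t, ok in zip(traits.trait_ids, complete) if not ok]
    if dropped:
        logger.info(
            "drop_incomplete: removed %d of %d traits (e.g. %s)",
            len(dropped), traits.n_traits, ", ".join(dropped[:5]),
        )
        return traits.take_traits(np.flatnonzero(complete))
    return traits


# ---------------------------------------------------------------------------
# writers


def write_peaks(peaks: pd.DataFrame, path: str | Path, float_fmt: str = "%.6g") -> None:
    """Write a per-trait peak table (trait_id, marker_id, chromosome,
    position_cM, lod) as TSV."""
    peaks.to_csv(path, sep="\t", index=False, float_format=float_fmt)


def write_lod_matrix(
    lod: np.ndarray,
    trait_ids: Sequence[str],
    marker_ids: Sequence[str],
    path: str | Path,
    float_fmt: str = "%.6g",
) -> None:
    """Write the full traits x markers LOD matrix as TSV (marker-id header,
    trait ids in the first column)."""
    df = pd.DataFrame(lod, index=list(trait_ids), columns=list(marker_ids))
    df.to_csv(path, sep="\t", index_label="trait_id", float_format=float_fmt)
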