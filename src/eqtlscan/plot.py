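"""Trans-eQTL map: peak position vs cognate-gene position.

Each trait with a peak LOD above the threshold contributes one point:
x is the genomic position of its best marker, y the position of the gene
the transcript derives from.  Points on the diagonal are cis (local)
eQTL; vertical bands off the diagonal are trans hotspots.  Traits without
a known cognate-gene position are not shown.

Genome coordinates concatenate chromosomes in numeric-then-alphabetic
order with cumulative offsets; physical (Mb) positions are used when the
annotation provides them, otherwise genetic (cM) positions.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

logger = logging.getLogger("eqtlscan")

_POSITION_COLS = ("position_Mb", "Mb", "position_cM", "cM", "position")


def _chrom_sort_key(label: str):
    s = str(label)
    return (0, int(s)) if s.isdigit() else (1, s)


def norm_chrom(value) -> str:
    """Canonical chromosome label: integer-like values lose any '.0'
    (pandas floats a chromosome column when blanks make it numeric)."""
    s = str(value).strip()
    try:
        f = float(s)
        if f.is_integer():
            return str(int(f))
    except ValueError:
        pass
    return s


def _annotation_position(annotation: pd.DataFrame) -> tuple[pd.Series, str]:
    for col in _POSITION_COLS:
        if col in annotation.columns:
            unit = "Mb" if "Mb" in col else "cM"
            return annotation[col].astype(float), unit
    raise ValueError(
        f"annotation needs one of {_POSITION_COLS} alongside 'chromosome'"
    )


def genome_offsets(
    chromosomes: pd.Series, positions: pd.Series, pad: float = 0.0
) -> tuple[dict, float]:
    """Cumulative per-chromosome offsets for a concatenated genome axis."""
    lengths = (
        pd.DataFrame({"chrom": chromosomes.astype(str), "pos": positions})
        .groupby("chrom")["pos"].max()
    )
    offsets, total = {}, 0.0
    for chrom in sorted(lengths.index, key=_chrom_sort_key):
        offsets[chrom] = total
        total += float(lengths[chrom]) + pad
    return offsets, total


def plot_eqtl_map(
    peaks: pd.DataFrame,
    annotation: pd.DataFrame,
    lod_threshold: float = 5.0,
    out_path: str | Path = "eqtl_map.png",
) -> int:
    """Scatter peak-marker position against cognate-gene position.

    ``peaks`` is a scan peak table (trait_id, marker_id, chromosome,
    position_cM, lod); ``annotation`` maps trait_id to the cognate gene's
    chromosome and position (Mb preferred, cM accepted).  Returns the
    number of points drawn; an empty plot is still written, with a warning.
    """
    ann = annotation.copy()
    if "trait_id" in ann.columns:
        ann = ann.set_index("trait_id")
    pos, unit = _annotation_position(ann)
    ann = pd.DataFrame({"gene_chrom": ann["chromosome"].map(norm_chrom), "gene_pos": pos})
    ann = ann.dropna()

    sel = peaks[peaks["lod"] > lod_threshold].copy()
    sel["chromosome"] = sel["chromosome"].map(norm_chrom)
    sel = sel.join(ann, on="trait_id", how="inner")

    # shared coordinate system across both axes
    all_chroms = pd.concat([sel["chromosome"], ann["gene_chrom"]])
    all_pos = pd.concat([sel["position_cM"], ann["gene_pos"]])
    offsets, total = genome_offsets(all_chroms, all_pos)

    fig, ax = plt.subplots(figsize=(7, 7))
    n_points = len(sel)
    if n_points:
        x = sel["position_cM"].to_numpy() + sel["chromosome"].map(offsets).to_numpy()
        y = sel["gene_pos"].to_numpy() + sel["gene_chrom"].map(offsets).to_numpy()
        ax.scatter(x, y, s=6, alpha=0.6, edgecolors="none")
    else:
        warnings.warn(
            f"no peaks exceed LOD {lod_threshold}; writing an empty eQTL map",
            stacklevel=2,
        )
    for off in list(offsets.values())[1:]:
        ax.axvline(off, color="0.85", lw=0.5, zorder=0)
        ax.axhline(off, color="0.85", lw=0.5, zorder=0)
    ax.set_xlim(0, total or 1)
    ax.set_ylim(0, total or 1)
    ax.set_xlabel(f"eQTL peak position (concatenated genome, {unit})")
    ax.set_ylabel(f"cognate gene position (concatenated genome, {unit})")
    ax.set_title(f"eQTL map (peak LOD > {lod_threshold:g}, {n_points} transcripts)")
    mids = {c: offsets[c] for c in offsets}
    ax.set_xticks(list(mids.values()), list(mids.keys()), fontsize=6, rotation=90)
    ax.set_yticks(list(mids.values()), list(mids.keys()), fontsize=6)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    logger.info("plot_eqtl_map: %d points -> %s", n_points, out_path)
    return n_points
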