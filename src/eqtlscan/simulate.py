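"""Synthetic recombinant-inbred (RI) panel generator.

Emulates a fully inbred two-founder panel (BXD-like): every strain is a
mosaic of two parental genomes, so marker dosages take just two values,
0 or 1.  Along each chromosome a strain's genotype is a two-state Markov
chain: the first marker is Bernoulli(1/2) and adjacent markers flip with
the recombination fraction implied by their cM separation under the
Haldane map function r = (1 - exp(-2d/100))/2, optionally expanded to
R = 4r/(1+6r) for RI lines produced by sib mating.  Chromosomes and
strains are independent.

Traits are linear in one planted marker's standardized dosage with unit
Gaussian noise: y = beta * z(g_q) + eps, beta = sqrt(h2/(1-h2)), so the
population fraction of variance explained by the eQTL equals the target
heritability h2.  Traits without a planted eQTL are pure N(0, 1) noise.
The planted marker, effect and noise scale per trait are returned as a
ground-truth table for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .io import GeneticMap, GenotypeMatrix, TraitMatrix, write_geno

TRUTH_COLUMNS = [
    "trait_id", "has_qtl", "marker_index", "marker_id",
    "chromosome", "position_cM", "beta", "noise_sd",
]


@dataclass
class SimConfig:
    """Panel-generation settings.

    Defaults describe a BXD-scale experiment: 80 strains genotyped on a
    20-chromosome, 100 cM-per-chromosome map at 2 cM marker spacing, with
    1000 expression traits of which 30% carry a single eQTL explaining
    h2 = 0.4 of the trait variance.
    """

    n_strains: int = 80
    n_chromosomes: int = 20
    chr_length_cM: float = 100.0
    marker_spacing_cM: float = 2.0
    n_traits: int = 1000
    prop_with_qtl: float = 0.3
    h2: float = 0.4
    map_function: Literal["haldane", "haldane_ri_expanded"] = "haldane"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_strains < 4:
            raise ValueError("n_strains must be at least 4")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be at least 1")
        if self.chr_length_cM <= 0 or self.marker_spacing_cM <= 0:
            raise ValueError("chromosome length and marker spacing must be positive")
        if self.marker_spacing_cM > self.chr_length_cM:
            raise ValueError("marker spacing exceeds chromosome length")
        if not 0.0 <= self.prop_with_qtl <= 1.0:
            raise ValueError("prop_with_qtl must be in [0, 1]")
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("h2 must be in [0, 1); h2 = 1 is degenerate (no noise)")
        if self.map_function not in ("haldane", "haldane_ri_expanded"):
            raise ValueError("map_function must be 'haldane' or 'haldane_ri_expanded'")


def haldane_recombination(d_cm: np.ndarray, expanded: bool = False) -> np.ndarray:
    """Recombination fraction for a map distance in cM.

    Haldane: r = (1 - exp(-2d/100)) / 2; with ``expanded`` the RI-by-sib-
    mating map expansion R = 4r/(1 + 6r) is applied.
    """
    d = np.asarray(d_cm, dtype=float)
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    if expanded:
        r = 4.0 * r / (1.0 + 6.0 * r)
    return r


def make_map(config: SimConfig) -> GeneticMap:
    """Evenly spaced markers at 0, s, 2s, ... up to the chromosome length."""
    ids, chroms, pos = [], [], []
    per_chr = int(np.floor(config.chr_length_cM / config.marker_spacing_cM)) + 1
    for c in range(1, config.n_chromosomes + 1):
        for k in range(per_chr):
            ids.append(f"c{c}m{k}")
            chroms.append(str(c))
            pos.append(k * config.marker_spacing_cM)
    return GeneticMap(
        np.array(ids, dtype=object), np.array(chroms, dtype=object), np.array(pos)
    )


def simulate_genotypes(
    gmap: GeneticMap, config: SimConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Draw 0/1 dosages for every strain as per-chromosome Markov chains."""
    if rng is None:
        rng = np.random.default_rng([config.seed, 0])
    n = config.n_strains
    expanded = config.map_function == "haldane_ri_expanded"
    dosage = np.empty((n, len(gmap)), dtype=float)
    for chrom in pd.unique(gmap.chromosomes):
        cols = np.flatnonzero(gmap.chromosomes == chrom)
        pos = gmap.positions_cm[cols]
        r = haldane_recombination(np.diff(pos), expanded=expanded)
        state = rng.random((n, len(cols)))
        first = state[:, 0] < 0.5
        flips = state[:, 1:] < r[None, :]
        # cumulative XOR of flip indicators gives the chain state
        chain = np.concatenate([first[:, None], flips], axis=1)
        dosage[:, cols] = np.logical_xor.accumulate(chain, axis=1).astype(float)
    strain_ids = [f"RI{i + 1:03d}" for i in range(n)]
    return GenotypeMatrix(dosage, strain_ids, gmap)


def simulate_traits(
    geno: GenotypeMatrix, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[TraitMatrix, pd.DataFrame]:
    """Plant single-marker eQTL into a fraction of traits.

    Returns the trait matrix and a truth table (one row per trait):
    trait_id, has_qtl, marker_index, marker_id, chromosome, position_cM,
    beta, noise_sd.  With h2 = 0 every trait is null.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    n, p = geno.n_strains, geno.n_markers
    m = config.n_traits
    gmap = geno.map
    beta = np.sqrt(config.h2 / (1.0 - config.h2)) if config.h2 > 0 else 0.0
    has_qtl = (rng.random(m) < config.prop_with_qtl) & (config.h2 > 0)
    # planted markers must be polymorphic in the realized panel
    variances = geno.dosage.var(axis=0)
    polymorphic = np.flatnonzero(variances > 0)
    if polymorphic.size == 0:
        raise ValueError("no polymorphic markers to plant eQTL on")
    planted = rng.choice(polymorphic, size=m)
    planted[~has_qtl] = -1

    Y = rng.standard_normal((n, m))
    for i in np.flatnonzero(has_qtl):
        g = geno.dosage[:, planted[i]]
        z = (g - g.mean()) / g.std()  # population sd; marker is polymorphic
        Y[:, i] += beta * z
    trait_ids = [f"T{i + 1:04d}" for i in range(m)]
    truth = pd.DataFrame(
        {
            "trait_id": trait_ids,
            "has_qtl": has_qtl,
            "marker_index": planted,
            "marker_id": [
                gmap.marker_ids[q] if q >= 0 else "" for q in planted
            ],
            "chromosome": [
                gmap.chromosomes[q] if q >= 0 else "" for q in planted
            ],
            "position_cM": [
                gmap.positions_cm[q] if q >= 0 else np.nan for q in planted
            ],
            "beta": np.where(has_qtl, beta, 0.0),
            "noise_sd": np.ones(m),
        }
    )
    traits = TraitMatrix(Y, geno.strain_ids, trait_ids)
    return traits, truth


def simulate_panel(
    config: SimConfig | None = None, **overrides
) -> tuple[GenotypeMatrix, TraitMatrix, pd.DataFrame]:
    """Map + genotypes + traits in one call; deterministic in config.seed."""
    if config is None:
        config = SimConfig(**overrides)
    gmap = make_map(config)
    geno = simulate_genotypes(gmap, config)
    traits, truth = simulate_traits(geno, config)
    return geno, traits, truth


def write_panel(
    geno: GenotypeMatrix,
    traits: TraitMatrix,
    truth: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Emit .geno / trait CSV / truth TSV files for end-to-end runs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "geno": outdir / "panel.geno",
        "traits": outdir / "traits.csv",
        "truth": outdir / "truth.tsv",
    }
    write_geno(geno, paths["geno"])
    pd.DataFrame(
        traits.values, index=traits.strain_ids, columns=traits.trait_ids
    ).to_csv(paths["traits"], index_label="strain")
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    return paths
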