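# eqtlscan

Fast bulk eQTL genome scans for two-genotype-class crosses (backcrosses and
recombinant inbred panels such as the BXD mouse family).

An eQTL study asks, for every one of thousands to millions of expression
traits, which genetic marker best explains its variation across strains.
Done naively this is `m × p` separate regressions. For a population with
only two genotype classes and a one-degree-of-freedom test, the whole scan
collapses into dense linear algebra: for trait *i* and marker *j*,

    LOD_ij = (n/2) log10(RSS0_i / RSS1_ij) = -(n/2) log10(1 - r_ij²)

where `r_ij` is the Pearson correlation between trait and marker dosage.
With column-standardized trait and genotype matrices `Y*` (n × m) and `G*`
(n × p), the full correlation matrix is a single product,

    R = (1/n) Y*′ G*

and the LOD matrix is an element-wise transform of `R`. Covariates `Z`
(including an intercept) are absorbed by projecting both `Y` and `G` onto
the orthogonal complement of the covariate space (residuals after
regressing on `Z` — the projector is never formed) before standardizing.
The scan optionally reduces each trait to its best marker (max mode), so
the m × p matrix never has to be materialized, runs in single or double
precision, and filters markers by minor allele frequency first.

The package is aimed at people mapping expression (or any other
high-dimensional omics) traits in experimental crosses who want
interactive-speed scans plus a trustworthy reference implementation: a
deliberately slow nested-regression oracle (`eqtlscan.oracle`) reproduces
every LOD score by explicit least squares and backs the test suite, and a
seeded recombinant-inbred simulator (`eqtlscan.simulate`) provides panels
with planted eQTL for validation end to end.

## Worked example

Simulate an 80-strain RI panel (5 chromosomes of 100 cM at 2 cM marker
spacing, 200 traits, 30% carrying one eQTL at heritability 0.5), scan it,
and draw the eQTL map:

```bash
eqtlscan simulate --n-strains 80 --n-chr 5 --chr-length-cm 100 --spacing-cm 2 \
    --n-traits 200 --prop-qtl 0.3 --h2 0.5 --seed 42 --out demo
eqtlscan scan --geno demo/panel.geno --traits demo/traits.csv --output-mode max --out demo
eqtlscan plot --peaks demo/peaks.tsv --annotation demo/truth.tsv --lod-threshold 5 --out demo/map.png
```

which prints

```
wrote demo/panel.geno (80 strains x 255 markers), demo/traits.csv (200 traits), demo/truth.tsv
wrote demo/peaks.tsv (200 traits)
wrote demo/map.png (58 transcripts above LOD 5)
```

`peaks.tsv` holds one row per trait — its best marker and score:

```
trait_id	marker_id	chromosome	position_cM	lod
T0001	c3m24	3	48	2.09959
T0002	c4m44	4	88	11.1101
T0003	c1m0	1	0	1.74713
```

T0002's peak LOD of 11.1 at c4m44 means the marker model is 10^11.1 times
more likely than the no-eQTL null; at h2 = 0.5 and n = 80 the expected
peak LOD is about -(80/2)·log10(0.5) ≈ 12, so this is a typical planted
hit, while scores near 1–2 (T0001, T0003) are noise. In this run all 58
traits with peak LOD > 5 are exactly the 58 simulated eQTL traits. The
plot places each such trait at (peak position, cognate-gene position);
with the planted marker used as the "gene", points line up on the
diagonal.

The same pipeline as a library, scikit-learn style:

```python
from eqtlscan import GenomeScan, SimConfig, simulate_panel

geno, traits, truth = simulate_panel(SimConfig(seed=42))
scanner = GenomeScan(output_mode="max", maf_threshold=0.05).fit(geno, traits)
print(scanner.peaks_.head())
```

Real data enters through `read_geno` (GeneNetwork-style `.geno` files,
codes B/D/H/U), `read_traits` / `read_covariates` (delimited text), then
`align_strains` and `drop_incomplete` before `fit`.

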