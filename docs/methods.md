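# Methods

## Model

For each expression trait `y_i` (length-n vector over strains) and marker
`j` with dosage `g_j`, the scan fits the univariate linear model

    y_i = X_j β_j + ε_i,   ε_i ~ N(0, σ_i² I)

with `X_j = [1, g_j]` (plus covariates when given) and tests the marker by
a one-degree-of-freedom likelihood ratio, reported as a LOD score

    LOD_ij = (n/2) log10(RSS0_i / RSS1_ij)

with RSS0 and RSS1 the residual sums of squares of the nested designs
without and with the marker. Because the test has one df and the genotype
is a single column, this is algebraically identical to

    LOD_ij = -(n/2) log10(1 - r_ij²)

with `r_ij` the Pearson correlation of trait and dosage. The scan engine
exploits the identity: standardize the trait and genotype matrices column
by column (mean 0, population variance 1), form `R = (1/n) Y*′G*` with one
dense matrix product, and apply the element-wise transform. The
brute-force oracle (`eqtlscan.oracle`) instead fits both nested
regressions explicitly per pair via QR; the identity holding to ~1e-14
between the two, with and without covariates, is the package's core
regression test.

Assumptions: two genotype classes (dosage effectively binary, though H =
0.5 calls are accepted), a purely additive single-marker model, Gaussian
errors, no kinship/polygenic term (a linear mixed model is out of scope),
and complete data — missing values must be resolved beforehand
(`drop_incomplete` removes affected traits; nothing is imputed).

## Covariates

With covariate block `Z` (intercept first), both `Y` and `G` are replaced
by their residuals after regressing on `Z` — the action of the projector
`P = I − Z(Z′Z)⁻¹Z′`, computed from the thin QR factor of `Z`; the n × n
projector is never formed. Standardizing the residuals and multiplying
yields the partial correlation, and the LOD identity then reproduces the
nested-regression score with `[Z, g_j]` as the full design exactly (the
test suite checks this to 1e-8 elementwise). The `n` in the LOD formula
is the aligned sample size and is deliberately not reduced by the number
of covariates; this follows the correlation identity rather than an
F-test degrees-of-freedom convention, and slightly inflates scores when
covariates are many and n is small.

## Numerical choices

- **Standardization** uses the population (1/n) variance so that
  `(1/n) Y*′G*` is exactly Pearson correlation. Columns whose standard
  deviation is at rounding level for their magnitude are treated as
  constant: zeroed, masked, and given correlation 0 / LOD 0 rather than
  NaN, so a stray monomorphic column cannot poison the max reduction.
- **Clamping**: r² is capped at 1 − 1e-12 before the log, so a trait that
  duplicates a marker yields the finite ceiling LOD = 6n instead of
  infinity. The oracle applies the same floor to RSS1/RSS0, keeping the
  two paths comparable at the edge.
- **log1p**: the LOD transform is `log1p(−r²)/ln10 · (−n/2)`, accurate for
  the tiny r² that dominate a null scan.
- **Precision**: all scan arithmetic (projection, standardization,
  product, transform) runs in the configured dtype. float64 is the
  default; float32 halves memory and is typically within ~1e-5 of the
  double-precision LOD wherever LOD ≤ 25 on an 80-strain panel (the test
  suite enforces ≤ 1e-3), so single precision is safe for peak finding
  but not for reporting many digits.
- **Chunking**: traits are processed in blocks (default 10,000 columns);
  in max mode only each trait's best marker index and score are kept, so
  the m × p matrix never exists in memory. BLAS blocking makes LOD values
  differ across chunk sizes only at the ~1e-14 level; peak marker indices
  are invariant, with ties broken toward the lowest marker index for
  determinism.
- **MAF filter**: markers with `min(f, 1−f)` below the threshold
  (default 0.05, f = mean dosage) are dropped before projection and
  standardization, on raw dosages.
- **Backend seam**: the dense cross-product is routed through
  `eqtlscan.scan.BACKENDS`, a one-function registry, so an accelerator
  (GPU) backend can be slotted in; only the CPU backend is provided and
  tested.

## Synthetic panels

`eqtlscan.simulate` generates fully inbred two-founder panels. Marker maps
are evenly spaced per chromosome; genotypes follow a two-state Markov
chain along each chromosome with flip probability given by the Haldane
map function `r = (1 − e^(−2d/100))/2` for inter-marker distance d cM,
optionally expanded to `R = 4r/(1+6r)` for RI lines by sib mating
(default: plain Haldane). Chromosomes and strains are independent; the
first marker of each chromosome is Bernoulli(1/2).

Traits are `y = β·z(g_q) + ε` with `z` the standardized dosage of one
uniformly chosen polymorphic marker, `ε ~ N(0,1)` and `β = √(h2/(1−h2))`,
so the population variance fraction explained by the eQTL equals h2
(noise variance is pinned at 1 so effect size and noise are not
confounded). Defaults — 80 strains, 20 chromosomes × 100 cM at 2 cM
spacing, 1000 traits, 30% with an eQTL at h2 = 0.4 — describe a
BXD-scale experiment and are what the tests and the acceptance script
call "the standard panel". Fixed seeds make every output bit-identical
across runs.

What the simulator does *not* emulate: genotyping error, missing data
patterns, heterozygosity, segregation distortion, polygenic background,
epistasis, shared-environment correlation between traits, and non-Gaussian
expression noise. Passing tests therefore demonstrate the algebra and the
engineering of the scan, not robustness to real-data artifacts; on real
panels the usual pre-processing (normalization, outlier handling,
covariate choice) remains the user's responsibility.

## Validation summary

The test suite and `scripts/acceptance.py` compute (never hard-code):
the RSS-vs-correlation identity residual over ≥100 random draws at
n ∈ {10, 80, 200}; elementwise agreement (≤1e-8) between the fast scan
and the regression oracle on an 80 × 500 × 200 panel with and without two
covariates; max/full-mode and chunk-size consistency of peaks;
closed-form spot values (r² = 0.9, n = 10 → LOD 5); ≥90% of planted eQTL
recovered within 10 cM at n = 100, h2 = 0.4 (typically ~98%); uniformity
of null-scan peak chromosomes (χ² goodness of fit); mean n·r² ≈ 1 for
null traits at a fixed marker; and the single-vs-double precision gap.
Problem sizes were chosen so the whole suite runs in about a minute on
one CPU while keeping every check at realistic panel scale.

## Known limitations

- One-df tests only; no multi-allelic or >2-founder encodings.
- No permutation-based significance thresholds; the LOD > 5 convention
  used in examples is a reporting choice, not a calibrated genome-wide
  threshold.
- No linear mixed model: relatedness beyond what covariates capture will
  inflate LOD scores.
- Max mode reports one peak per trait; traits with multiple eQTL need a
  follow-up scan restricted to the traits of interest.
- The eQTL-map plot needs peak and annotation positions on a common scale
  (both cM or both Mb); it does not convert between maps.
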