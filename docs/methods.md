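# Methods

This note documents the models implemented in `polyhub`, the parameters
that matter, and the design decisions taken where conventions differ
between tools. Every number quoted here is computed by the test suite or
`scripts/acceptance.py`; nothing is asserted that the code does not measure.

## Synthetic data model

The generator produces every input the pipeline consumes, on a small
multi-chromosome genome (default 2–3 chromosomes of 5–30 Mb at 10 kb
resolution). All samplers take an explicit seed and are byte-deterministic.

**Intervals.** Domains, TADs, peaks and baits are placed without overlap by
apportioning intervals to chromosomes in proportion to length and
distributing the free space uniformly between them. Default domain count
(2,097 on the larger default genome) and lengths (5–20 kb) mirror the scale
of Polycomb domains relative to a mammalian genome; on the compact genomes
used for contact-map simulations the density is kept proportionate.

**Hi-C.** Expected intensity is a power-law distance decay
`(1 + d)^-alpha` (default `alpha = 1`, the classic intra-chromosomal
exponent) multiplied by block factors: ×2 inside TADs, ×3 at loop-anchor
pixels, and a condition-specific hub factor on domain-pair blocks (default
WT 3×, KO 1× — the hub collapse being the effect under study). Counts are
Poisson draws of the upper triangle, mirrored, so matrices are exactly
symmetric; `depth` is the expected total count of the full matrix
(default 8–16 M over the simulated genome, i.e. a scaled-down deep Hi-C).

**ChIP.** Per-bin target IP counts are Poisson with mean proportional to
`occupancy x ip_efficiency`; spike-in IP counts are proportional to
`ip_efficiency` alone; inputs see neither. Domain occupancy defaults to 8×
background in WT and 4× in KO (a 2-fold occupancy loss). `ip_efficiency`
can differ per condition precisely to create the confound that spike-in
calibration must remove. Defaults: 3 replicates, 5% spike-in fraction,
1–2 M reads per library.

**Capture-C.** Virtual fixed-length restriction fragments (500 bp) stand in
for DpnII fragments; motif-based digestion would add no tested behaviour.
Per-bait counts decay as `(1 + d/20 kb)^-1` and are multiplied by the hub
factor at fragments inside hub-partner domains. Interaction scores are
drawn from two separated gamma families — `5 + Gamma(2, 2)` for hub
partners in an interacting condition (hub factor > 1), background
`min(Gamma(2, 0.6), 4.99)` otherwise — so the ≥ 5 cutoff separates the two
classes by construction; the upstream score-calling model itself is out of
scope and scores are treated as inputs throughout the quantification code.

**Expression.** Negative-binomial counts (`var = mu + alpha mu^2`,
dispersion `alpha = 0.05`) around lognormal base means (median ≈ 100
counts), 4 replicates per condition, with three kinds of truth: per-gene
log2 fold changes, an optional global multiplier on all target genes in one
condition (spike-in genes never change), and a three-condition
differentiation design (ESC → differentiated WT/KO) where induced genes
carry +3 log2 units and "dependent" genes lose 2 of them in the KO. The
scaled-down defaults (2,000 genes, 300 induced, 100 dependent) keep the
recovery analyses well-powered in seconds.

## Spike-in calibration

Reported per IP sample: spike-in ratio `r = spike_total/target_total`,
input correction `c = input_target_total/input_spike_total`, effective
spike-in coverage `f = spike_total x c`, and downsampling fraction
`p = min(f)/f`. Downsampling to a common input-corrected spike-in coverage
is the anchoring that makes between-sample target ratios proportional to
occupancy: under the generative model above, `f` scales with IP efficiency
and sequencing depth but not with target occupancy, while the input
correction cancels variation in the spike-in mixing proportion. Scaling to
the *minimum* `f` guarantees every fraction is ≤ 1 (no sample is ever
upsampled) and exactly one sample keeps all reads. Thinning is per-interval
binomial — expectation-equivalent to read-level subsampling and testable in
closed form — and never touches the spike-in compartment. Factors are
computed per replicate; replicates are pooled only after calibration.
Calibration is skippable for experiments run without spike-in.

## Signal quantification

Coverage is a per-bp vector per chromosome; interval counts are plain
half-open sums (verified against a per-bp brute force). Heatmap rows are
binned windows (default ±2.5 kb, 50 bp bins) centred on the interval
midpoint, or on the strand-aware start for TSS anchors, with minus-strand
rows reversed; windows leaving the chromosome are zero-padded and flagged.
Rows sort by decreasing reference signal with ties broken on anchor id.
Replicate QC computes Pearson's r and warns (without failing) below the
conventional 0.9 pooling bar.

## Hi-C aggregates

**ICE.** Iterative correction with a per-iteration bias update; bins with
zero coverage are masked. Convergence: maximum relative deviation of
unmasked row sums ≤ `tol` (default 1e-5) within `max_iter` (200);
non-convergence raises an error carrying the last residual. Balanced
matrices are rescaled so unmasked marginals share a common mean.

**Observed/expected.** Expected is the per-chromosome mean of each diagonal
(distance). This makes a pure distance-decay matrix aggregate to exactly 1
and removes decay from all aggregate maps.

**APA** (half-window 10 bins → 21×21 at 10 kb): mean O/E submatrix around
each loop pixel; pairs closer than 2× the half-window to the diagonal, or
with windows leaving the matrix, are skipped. The enrichment score divides
the center pixel by the mean of the short-range corner quadrant (a local
background at shorter distance on both axes).

**ATA** (grid 100): each TAD plus 50% flanks is rescaled to the grid by
area-weighted interpolation (fractional bin overlaps, rows normalized), and
frames are averaged. TADs shorter than 5 bins are skipped.

**PE-SCAn**: every same-chromosome anchor pair with separation in
[`min_sep`, `max_sep`] (defaults 200 kb–5 Mb) contributes the O/E submatrix
spanning `flank` around each anchor. Winsorization clamps the pooled pixel
values at the `trim`/`1−trim` quantiles before averaging. Two presets:
`polycomb` (100 kb flanks, 10 kb bins, no trimming) and `super_enhancer`
(1 Mb flanks, 20 kb bins, 5% trimming). Trimming is deliberately off in the
polycomb preset: when fewer than 5% of pooled pixels carry the enrichment
being measured, a 5% winsorization would clamp the signal itself.

**Domain-pair difference maps**: the same extraction with 200 kb flanks
around domain midpoints in two conditions, element-wise WT−KO; only pairs
usable in both conditions contribute, so the difference is paired.

**Estimator bias, and why recovery uses sparse implants.** Two properties
of these aggregates matter when validating against ground truth. First,
block enrichments inflate their own distance-expectation, deflating O/E
everywhere at the affected distances (a single TAD covering 20% of a
chromosome depresses its apparent enrichment by ~30%; at 4% coverage the
effect is a few percent). Second, ICE forces equal marginals, so rows
carrying genuine biological enrichment are scaled down, shaving a further
few percent off dense hub blocks. Both are intrinsic to the standard
analysis, not artifacts of this implementation; the recovery analyses
therefore implant *sparse* features (single-bin domains, ≲3 partners per
anchor, ~1000-bin matrices), under which the implanted 3× factor is
recovered within sampling error (center ≈ 2.97 ± 0.11 over seeds). Dense
configurations remain available and show the documented suppression.

## Capture-C quantification

`cov` in the normalization is the sample's total captured read count across
all baited fragments (the per-sample reading; a per-bait variant is noted
as an open alternative). Normalized counts therefore sum to
`nprom x 100000` exactly and are invariant to uniform depth changes. A
promoter–interval pair qualifies when ≥ 1 overlapping fragment reaches the
score threshold (default 5), but its means run over *all* overlapping
fragments — the literal two-step reading of the called-interaction rule.
Overlap is any-basepair, half-open. For between-condition boxplots the
summary offers two modes: `each` (qualification applied within each
condition; the literal rule) and `union` (pairs qualifying in any condition
are reported in all of them), the latter used for WT/KO comparisons so both
distributions cover the same interaction set — otherwise a condition with
collapsed interactions contributes almost no qualifying pairs and its
median is undefined rather than reduced. Pairs are deliberately not
distance-matched. Quartiles use linear interpolation between order
statistics; whiskers clip to the most extreme observation within 1.5×IQR
(collapsing onto the box edge when no observation lies between a quartile
and its fence); the notch half-width is `1.58 x IQR / sqrt(n)`.

## Differential expression

Size factors are median-of-ratios on spike-in genes only (geometric-mean
reference excluding genes with any zero count; no pseudocounts), rescaled
to geometric mean 1, then applied to target genes. A library-size ablation
(`libsize_size_factors`) exists to demonstrate what spike-in anchoring
buys: under a global shift it reports median log2FC ≈ 0 where spike-in
anchoring reports the true shift.

The test is a transparent NB Wald test rather than a full shrinkage
estimator: per-condition means of normalized counts, variance
`(1/n^2) sum(mu/s_i + alpha mu^2)`, two-sided normal p-value, BH
adjustment. The dispersion entering the variance is, by default, the
*mean* of the per-gene moment estimates shared across genes. Per-gene
moment estimates from 3–4 replicates are individually so noisy that using
them directly makes the normal reference anticonservative (~2× the nominal
type-I rate), and their *median* underestimates the common dispersion
because the estimator's sampling distribution is chi-square-skewed; the
across-gene mean is unbiased under the generator's constant-dispersion
model and yields a null type-I rate statistically indistinguishable from
0.05 at 2,000 genes. `dispersion="per-gene"` retains the raw estimates.
Genes with zero mean in either condition are flagged untestable and
excluded from the adjustment. Classification uses strict inequalities:
up if fold > 1.5 and padj < 0.05, down symmetrically on the linear scale.

"Dependent" genes are called from two pairwise contrasts — up in
(differentiated WT vs ESC) and down in (differentiated KO vs WT) — each
with its own spike-in factors computed on the combined pair of tables; an
interaction-term formulation would be an alternative, but pairwise
contrasts match how the selection is described and are directly testable
against simulation truth.

## Pipeline

`run_all` derives one seed per stage from the master seed and a stable
stage-name hash (all seeds < 2^31), writes plain-text TSV/BED/JSON
artifacts only, and is byte-deterministic for a fixed config. Stage
failures halt the run with a stage-attributed error. The CLI (`polyhub`)
exposes each stage over the same TSV formats.

## Problem sizes and runtime

Simulations are sized for a single CPU: contact maps of 500–1,000 bins per
chromosome, 0.2–1 M reads per ChIP/Capture-C library, 2,000 genes × 8–12
samples. The full test suite runs in about a minute; the acceptance script
in ~20 s. These are scaled-down analogues of the real experiments; the
scaling affects statistical precision, not the code paths exercised.

## Limitations

The generator emulates the *statistical* structure of the data (decay,
block enrichments, count noise, confounds), not sequence-level reality: no
read-level simulation, no mappability or GC structure, no CNVs, flat
background coverage, constant expression dispersion, and an idealized
score distribution in place of the upstream interaction-caller. Passing
tests certify that the quantification machinery recovers known truth under
these conditions; they do not certify robustness to artifacts the
generator does not model. The NB Wald test deliberately omits dispersion
shrinkage and fold-change moderation, so on real data with gene-specific
dispersion trends it will be less well calibrated than a full DESeq2-style
fit.
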