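# Methods

## The measurement model

The pipeline analyses paired gene × sample intensity matrices from two RNA
channels of the same time-course experiment: nascent nuclear run-on RNA
(NRO, the "transactome") and whole-cell total RNA (the transcriptome).
Arrays are assumed to be on a raw positive intensity scale, optionally with
a per-gene per-sample detection score D ∈ [0, 1] (Illumina-style). The
design is a one-factor time course with a 0-hr baseline and replicate
arrays per timepoint; contrasts are always timepoint-vs-baseline within one
channel.

Genes whose detection score stays below the threshold (default D = 0.98) in
*every* sample are removed before any statistics; a single detected sample
retains the gene. The filter is idempotent and order-preserving.

## Normalization and the Z-ratio statistic

Each array is standardized independently: z = (log₁₀x − mean)/SD across its
genes, sample SD (n − 1 denominator, used everywhere in the package). This
removes per-array brightness and scale without between-array fitting, and
makes arrays exchangeable within a group.

For a contrast, the per-gene difference of replicate-averaged z-scores,
d_g, is divided by the sample SD of all d_g in the comparison, giving the
Z-ratio. Consequences worth knowing:

- The Z-ratio vector has sample SD exactly 1 (a construction identity, used
  as a self-check).
- Calibration rests on most genes being null. The shared denominator is
  estimated over *all* genes, so when a large coordinate fraction of the
  genome shifts, the denominator inflates and sensitivity drops. With ~5%
  of genes regulated at 2-fold and replicate noise of 0.2 log₂ units, the
  per-contrast detection power at p ≤ 0.001 is ≈ 0.99; at ~10% regulated it
  can fall below 0.6 at the late timepoint. This behaviour is intrinsic to
  the statistic, and it is why the simulator's default regulated fraction
  is 0.05 (see below).

p-values are two-sided standard-normal on the Z-ratio (the statistic is
population-standardized by construction); replicate-level t-statistics are
deliberately not the default. q-values are Benjamini–Hochberg. The compound
call is p ≤ 0.001 AND q ≤ 0.1 AND (fold effect ≥ 1.5 on the ratio scale OR
|Z-ratio| ≥ 3.0); the fold and Z-ratio clauses substitute for each other
(OR), since either one establishes a material effect size once the p/q
clauses establish significance. Fold changes are ratios of raw-scale
replicate means (not of z-scores); a signed convention (−1/ratio below 1)
is provided for reporting.

The qPCR utility implements the standard ΔΔCt quantification: fold =
2^(−mean ΔΔCt) over replicates.

## Waves, first appearance, and the NRO lead

For each channel, per-timepoint up-regulation flags are
`passes_filter AND direction == up` from the timepoint-vs-baseline DE
tables. The first appearance is the earliest flagged timepoint, NaN if
none. Wave classes, from the NRO first appearance:

- early: first_up ≤ 1 hr
- delayed_early: 1 < first_up ≤ 6 hr
- late: first_up > 6 hr (in the default grid, only the 48-hr point)
- unregulated: no first appearance.

Down-regulation waves can be obtained by passing down-flags; the default
follows the up-regulated convention. Transience is defined against the
final timepoint only: a gene (or set) that appeared earlier but is not
significant at the last timepoint is flagged transient; intermediate
dropouts do not toggle the flag — with noisy per-timepoint calls, requiring
contiguity would misclassify a large share of persistent genes.

The NRO lead is first_up(total) − first_up(NRO), summarized by its median
and the fraction ≥ 0 over genes regulated in both channels.

## PAGE / GSMA

Z = (Sm − µ)·√m/σ per set per contrast, with µ and σ the median and sample
SD of all log-ratios in the contrast and Sm the median over the m set
members present among the measured genes (absent members are dropped; m
reflects the intersection; even-sized medians are midpoints). The
background universe defaults to all measured genes after detection
filtering — restricting to differentially expressed genes is supported
(`universe='de'`) but shrinks and biases σ, so it is not the default.

Because Sm is a median and σ an SD, the null SD of Z is near but not
exactly 1 (≈ 1.1–1.25 for m ≈ 20 under Gaussian log-ratios); Z is treated
as a ranking score, and the attached normal p/q values are a convenience.
Cells whose preconditions fail (no measured members, degenerate contrast)
are flagged missing, never zero, so ordering cannot mistake them for null
results. Set ordering uses the same first-appearance rule as genes, applied
to thresholded Z in the NRO contrasts, with never-significant sets last by
descending |Z| at the final NRO contrast.

## Clustering

Agglomerative complete linkage under distance 1 − uncentered Pearson
(cosine of raw profiles; sensitive to sign and magnitude, as appropriate
for log-ratio trajectories anchored at 0). Ties on merge distance are
broken toward the pair whose clusters carry the lexicographically smallest
leaf labels, making the dendrogram deterministic and input-order free.
Merge heights are non-decreasing (complete linkage is reducible). The
implementation is the package's own because of the specified tie-break;
tests verify exact agreement (cophenetic matrices and merge heights) with
scipy's independent implementation on random small instances. A cut-height
accessor yields flat clusters; no claim is made about reproducing any
particular published cluster size, which depends on a manual cut.

## Cross-platform concordance and direct targets

Tables are joined on uppercase, whitespace-stripped symbols; duplicates are
averaged as arithmetic means of log-ratios before an inner join. The
correlation matrix is centered Pearson. Direct-target calling intersects a
ChIP-bound list with significant up and down calls; genes called both up
and down are excluded from both sets and reported as conflicts.

## The synthetic generator

The generator emulates the study design the pipeline targets: seven
timepoints (0, 0.25, 0.5, 1, 3, 6, 48 hr), 6 replicate arrays per timepoint
(10 at 48 hr), both channels, with planted waves whose total-RNA onsets
trail NRO onsets by `lag_steps` grid positions (clamped at the final
point). Defaults, and why:

- `fraction_regulated = 0.05`. A single transcription factor's direct
  response is a few percent of the measured genome, and the Z-ratio's
  self-normalization presumes a mostly-null background (see above); 5%
  keeps the statistic in its calibrated regime while providing hundreds of
  planted genes at default sizes.
- `wave_mix = {early: .35, delayed_early: .35, late: .15,
  transient_early: .15}` — a front-loaded response with a persistent
  steady-state component and a visible transient population.
- `effect_log2 = 1` (2-fold), `noise_sd_log = 0.2`: signal and noise are
  both on the log₂ scale, giving a 5:1 per-replicate signal-to-noise —
  typical of a clearly regulated gene on bead arrays. Internally noise is
  applied as log₁₀ Gaussian of SD `noise_sd_log·log₁₀2`; keeping effect and
  noise on one scale makes the power of every downstream stage a function
  of their ratio alone.
- Baseline abundances: log₁₀ ~ N(2.5, 0.5) truncated > 0.5; background
  genes N(1.8, 0.3), with detection scores Uniform(0, 0.9) in every sample
  (expressed genes score 1). The detection score has no mechanistic
  definition here — only its threshold behaviour matters.
- Onset grids: early and transient waves draw uniformly from the grid
  points in (0, 1] hr, delayed-early from (1, 6] hr, late is the final
  point. Transient genes revert to expected log-ratio 0 at the final
  timepoint in both channels.
- Wave counts are exact (largest-remainder apportionment), so a request
  for 100 early genes plants exactly 100.

All randomness flows from one `numpy.random.default_rng(seed)`; identical
configs are bit-identical, which the run manifest verifies end to end with
SHA-256 hashes.

What the generator does **not** emulate: probe-level effects, intensity-
dependent (heteroscedastic) noise, correlated genes, partial detection,
RNA-stability differences between channels, or kinetic synthesis/decay
dynamics — planted effects are step functions. Passing recovery tests
therefore demonstrates correctness of the statistics and plumbing under the
stated model, not robustness to every artefact of real arrays.

Companion generators share the same truth table: gene-set collections with
planted single-wave sets and uniform null sets; two platform replicas of
the steady-state contrast with independent Gaussian platform noise
(expected inter-platform correlation v/(v + s²), the classical attenuation
formula, which the tests verify at v = s² → 0.5); and ChIP lists with a
coverage fraction of regulated genes plus unregulated decoys.

## Numerical choices

- Sample SD (n − 1) everywhere; log₁₀ before z-scoring, log₂ for reported
  ratios and folds.
- Degenerate arrays (within-array SD < 1e-12 of log intensities) and
  degenerate contrasts (zero SD) raise instead of returning NaNs.
- TSV floats are written as `%.17g` and read with round-trip parsing, so
  matrix write→read is bit-exact.
- Seeds: the orchestrator derives stage seeds as seed+1, +2, +3 for gene
  sets, platforms and ChIP lists, keeping stages independently reproducible.

## Problem sizes

Default verification sizes (chosen to characterize the statistics well
while keeping any laptop run in seconds): 20,000 genes for null
calibration; 4,000 genes × 92 arrays for recovery runs; 10,000 genes for
the attenuation check; 1,000 random instances for the PAGE oracle; 100
random instances of n ≤ 8 leaves for the clustering oracle.

## Known limitations

- The normal p-values on Z-ratios understate replicate-level uncertainty
  when replicate counts are very small and noise is heteroscedastic;
  moderated-variance statistics are out of scope by design.
- PAGE p-values inherit the median/SD mismatch noted above.
- Wave boundaries are calendar cutoffs on the default grid; custom grids
  map through the same ≤ 1 hr / ≤ 6 hr / later rule, which may not suit
  other biologies.
- No probe-to-gene summarization, RMA/quantile normalization, or
  exon-level analysis: inputs are expected pre-summarized, one row per
  gene symbol.
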