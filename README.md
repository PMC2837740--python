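# anro

Analysis of **array-based nuclear run-on (ANRO)** time courses: paired
measurements of nascent nuclear transcription (NRO RNA) and steady-state
mRNA (total RNA) on expression microarrays, taken at several timepoints
after induction of a transcription factor.

Standard expression profiling only sees steady-state mRNA, which confounds
transcription with RNA stability and lags behind the transcriptional events
that cause it. Capturing nascent RNA from isolated nuclei and hybridizing it
to the same arrays adds the missing layer — the *transactome* — so that one
can ask **when** each gene is first transcriptionally activated, how far
nascent transcription **leads** steady-state mRNA, and which bound
transcription-factor targets are actually **transcriptionally responsive**
(direct targets). The package implements the full desk-side analysis for
such experiments, together with a seeded simulator of an inducible-MYC
B-cell time course (0, 0.25, 0.5, 1, 3, 6, 48 hr; 6 replicate arrays per
timepoint, 10 at 48 hr) so every stage is testable against known ground
truth.

## Methods at the core

**Per-array normalization.** Each array is standardized on a stand-alone
basis: z = (log₁₀ x − mean) / SD over the genes of that array (sample SD,
n−1). No between-array fitting.

**Z-ratio differential expression.** For a contrast between two groups of
arrays, per gene d_g = mean(z_A) − mean(z_B), and

&nbsp;&nbsp;&nbsp;&nbsp;Z-ratio_g = d_g / SD({d_g : all genes}),

so the Z-ratio vector has sample SD exactly 1. Two-sided normal p-values,
Benjamini–Hochberg q-values, and the compound significance filter

&nbsp;&nbsp;&nbsp;&nbsp;p ≤ 0.001 AND q ≤ 0.1 AND (fold ≥ ±1.5 OR |Z-ratio| ≥ 3.0).

**Wave assignment.** A gene's *first appearance* is the earliest timepoint
at which it is called significantly up-regulated versus the 0-hr baseline.
Classified on the NRO channel: early (≤ 1 hr), delayed-early (3–6 hr), late
(final timepoint only), plus a *transient* flag when the gene is no longer
significant at the final timepoint. The lead of transcription over mRNA is
first_up(total) − first_up(NRO).

**Gene-set enrichment (PAGE / GSMA).** For gene set S in one contrast,

&nbsp;&nbsp;&nbsp;&nbsp;Z = (Sm − µ)·√m / σ,

with Sm the median log-ratio of the m measured set members, and µ, σ the
median and sample SD of all log-ratios in that contrast. Applied across all
contrasts (both channels × all timepoints) and sorted by first appearance in
the NRO channel, this exposes waves of coordinately transcribed pathways and
transcription-factor motif sets.

**Concordance and direct targets.** Contrast-level log-ratio tables from
different platforms are joined on uppercase HUGO symbols (duplicates
averaged) and compared by Pearson correlation; ChIP binding lists are
intersected with significant up/down calls to produce direct-target sets.

**Clustering.** Complete-linkage hierarchical clustering under the
uncentered-Pearson distance (1 − Σxy/√(Σx²Σy²)) with a deterministic
lexicographic tie-break, for heatmap-style gene ordering.

## Worked example

```python
import anro
from anro import preprocess, differential, timecourse

cfg = anro.SimConfig(n_genes=2000, seed=1)
nro, total, annot, truth = anro.generate_experiment(cfg)

de = {}
for name, mat in (("nro", nro), ("total", total)):
    filt = preprocess.filter_undetected(mat)      # drop background genes
    z = preprocess.ztransform_array(filt)         # per-array z-scores
    de[name] = differential.timepoint_de_tables(z, filt, annot)

de48 = de["nro"][48.0]
print(f"significant at 48 hr (NRO): {int(de48['passes_filter'].sum())} genes")

waves = timecourse.wave_table(de["nro"], de["total"])
print(waves.loc[truth["regulated"], "wave_class"].value_counts().to_string())
summary = timecourse.lead_lag(waves.loc[truth["regulated"]])
print(f"median NRO lead: {summary['median_lead_hr']:.2f} h "
      f"({100*summary['fraction_lead_nonneg']:.0f}% lead >= 0, n={summary['n']})")
```

prints

```
significant at 48 hr (NRO): 83 genes
wave_class
early            50
delayed_early    34
late             15
unregulated       1
median NRO lead: 0.50 h (100% lead >= 0, n=95)
```

The simulation planted 100 regulated genes (5% of 2000); 83 of the 85
persisting ones pass the compound filter at steady state, 99 of 100 land in
their planted wave class, and for the 95 genes detected in both channels the
total-RNA appearance trails the NRO appearance by a median of half an hour —
nascent transcription anticipates the transcriptome, as designed.

The same stages are available from the shell (`anro simulate`,
`anro preprocess`, `anro de`, `anro cluster`, `anro gsma`, `anro concord`,
`anro targets`), and `anro run --config run.yaml` drives the whole pipeline,
writing TSV/GMT artifacts and a manifest with SHA-256 hashes that are
bit-identical across reruns of the same config and seed.

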