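# adlpquant

Multi-batch **TMT 10-plex reporter-ion quantification and statistics
pipeline** for longitudinal mouse-model proteomics, built around the design
of a four-genotype Alzheimer's-disease hippocampus study: wild type (WT), an
amyloid-only model (APP_PS1), a tau-only model (Tau), and a double-pathology
model (APT), each sampled at 4, 7, and 10 months in biological triplicate —
36 samples distributed over four 10-plex TMT sets with a pooled-reference
channel (131), an ovalbumin spike-in in every channel, and duplicate MS runs
per set.

It is intended for proteomics analysts who have protein-group reporter-ion
tables (e.g. a Proteome Discoverer export converted to TSV) and want the
complete downstream workflow as reproducible, tested code:

* **Normalization** — spike-in scaling per (set, run, channel), technical
  duplicate merging, and the pooled-reference ratio ("normalized protein
  abundance"): `x_{p,sample} = I_{p,channel} / I_{p,pooled(set)}`, which
  bridges quantification across TMT batches.
* **Quantifiability filtering** — quantified in all channels → high
  identification confidence → ≥ 1 unique peptide, with the sequential
  cascade counts reported.
* **QC metrics** — spike-in CV across MS runs, duplicate-run R², between-set
  pooled-channel R², within-group replicate Pearson r.
* **Differential expression** — per-contrast Student's t-test vs age-matched
  WT with the dual threshold *p* < 0.05 and fold change > 1.25 (symmetric),
  and omnibus one-way ANOVA across (genotype, age) groups with
  Benjamini–Hochberg FDR < 0.05.
* **Profile clustering** — per-protein z-normalization + average-linkage
  hierarchical clustering (Euclidean), k chosen per question.
* **Exclusive DEP selection** — significant in the double-pathology model
  but quiet (FC < 1.25) in every single-pathology model at the same age.
* **Enrichment & networks** — one-sided Fisher-exact over-representation
  against GMT gene sets (background = quantified proteome), and PPI bridge
  analysis: proteins on short interaction paths between App and Mapt in a
  STRING-style edge list.
* **Synthetic data** — a seeded generator that emulates the full design
  (batch structure, pooled channel, spike-in, lognormal noise, planted
  up-/down-regulated archetypes), so the entire pipeline is testable and
  demonstrable without any download.

See `docs/methods.md` for the model, the noise calibration, and known
statistical properties.

## Worked example

Run the whole pipeline on a synthetic experiment from one config:

```bash
cat > config.yaml <<EOF
outdir: out
seed: 1
simulate: {n_proteins: 2000}
EOF
adlpquant run --config config.yaml
```

This writes the raw table, design, abundance matrix, QC report, nine t-test
contrast tables, ANOVA DEP sets, cluster assignments, exclusive DEPs,
enrichment results, the App–Mapt bridge report, and a `manifest.json` with a
checksum per artifact (re-running the same config reproduces identical
checksums).

The same analysis through the library:

```python
from adlpquant import (SimulationParams, simulate_dataset, spikein_normalize,
                       merge_technical_duplicates, filter_quantifiable,
                       compute_normalized_abundance, compute_qc_report, ttest_dep)

table, design, truth = simulate_dataset(SimulationParams(n_proteins=2000, seed=1))
filtered, report = filter_quantifiable(
    merge_technical_duplicates(spikein_normalize(table, design)), design)
matrix = compute_normalized_abundance(filtered, design)
qc = compute_qc_report(table, matrix, design)
apt10 = ttest_dep(matrix, "APT", 10)

print(report)
print(f"spike-in CV {qc.spikein_cv_percent:.1f}%  "
      f"duplicate R2 {qc.duplicate_r2_mean:.3f}  "
      f"set-to-set R2 {qc.set_to_set_r2_mean:.3f}")
print(f"APT 10 mo DEPs: {int(apt10.significant.sum())}")
```

Output (seed 1):

```
FilterReport(n_identified=2001, n_all_channels=1463, n_high_confidence=1448, n_unique_peptide=1447)
spike-in CV 6.1%  duplicate R2 0.998  set-to-set R2 0.993
APT 10 mo DEPs: 206
```

Reading it: of 2001 identified protein groups, 1447 survive the
quantifiability cascade (~72% complete in all channels, matching the design
of the emulated study); the spike-in varies by ~6% across the eight MS runs;
technical duplicates agree better than batches, which agree better than
biological replicates; and 206 proteins pass the dual significance threshold
in the double-pathology model at 10 months — amyloid-driven counts grow with
age while the tau-only model stays near-null, the qualitative signature the
generator plants.

Individual stages are also exposed as subcommands
(`adlpquant simulate|normalize|qc|dep|enrich|network`); see `--help`.

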