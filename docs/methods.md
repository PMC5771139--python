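# Methods

`adlpquant` implements the quantification and statistics workflow of a
multi-batch isobaric-labeling (TMT 10-plex) proteome study of four mouse
genotypes — wild type (WT), an amyloid-only model (APP_PS1), a tau-only
model (Tau), and a double-pathology model (APT) — sampled at 4, 7, and
10 months with three biological replicates each.  The 36 hippocampal
samples are distributed over four 10-plex TMT sets; each set carries nine
sample channels plus one pooled-reference channel (131) loaded with a pool
of all samples, and each labeled mixture is measured in two technical MS
runs.  An ovalbumin spike-in standard is present at constant amount in
every channel.

## Quantification model

Reporter-ion intensities are treated as multiplicative:

```
I(p, s, r, c) = signal(p, channel c) x set_scale(s) x channel_scale(s, c)
                x batch(p, s) x run_noise(p, s, r, c)
```

for protein group `p`, TMT set `s`, run `r`, channel `c`.  The chain of
estimators removes these factors step by step:

1. **Spike-in normalization.** Every (set, run, channel) is rescaled by
   `reference / spike-in intensity`, with the reference taken as the
   geometric mean of the spike-in over all designed channels.  The
   geometric mean makes the operation symmetric across channels and
   idempotent.  This removes `set_scale x channel_scale` exactly (up to the
   spike-in's own acquisition noise).  Normalization is applied per
   (set, run, channel) — the strictest granularity — because loading and
   acquisition variation act at the channel level.
2. **Technical-duplicate merging.** The two runs of a set are averaged
   per (protein, channel); a merged cell is missing only if it was missing
   in both runs.  Merging happens after spike-in normalization so run-level
   loading differences are removed before averaging.
3. **Quantifiability filter.** Protein groups are kept if (i) quantified in
   every designed channel of every set, (ii) identified at high confidence,
   (iii) supported by at least one unique peptide.  The three filters are
   applied sequentially and the count after each stage is reported, so the
   cascade can be compared against an experiment's printed numbers.
4. **Pooled-reference ratio ("normalized protein abundance").**  Each
   sample channel is divided by its set's pooled channel.  Because the
   pooled channel contains the same mixture in every set, this single
   division bridges quantification across batches and cancels every
   per-set factor that multiplies all channels of a set equally — including
   protein-specific batch effects from per-set digestion/labeling.
5. **Fold change.** Transgenic vs age-matched wild type, as the ratio of
   replicate means (stable under unequal replicate counts; a
   mean-of-ratios option exists).

## Statistical tests

* **Per-contrast DEPs**: two-sided Student's (pooled-variance) t-test of a
  transgenic group against age-matched WT on the untransformed normalized
  abundances (their distribution is near-normal after ratio formation; a
  log2 option and Welch's test are available).  Significance uses a dual
  threshold: `p < 0.05` and fold change `> 1.25` in either direction
  (`max(FC, 1/FC) > 1.25`); the symmetric reading is the default because
  both up- and down-regulation are of interest.
* **Omnibus DEPs**: one-way ANOVA per protein across an explicit list of
  (genotype, age) groups — all 12 cells for the all-model DEP set, the six
  APT/WT cells for the double-pathology set — with Benjamini–Hochberg
  step-up control at FDR 0.05 spanning all proteins of that one call.
  Rows that are constant across all groups are reported as F = 0, p = 1.
* **Profile clustering**: per-protein z-normalization across samples
  (zero-variance rows map to all-zero profiles) followed by average-linkage
  agglomerative clustering on Euclidean distance, cut at a user-chosen k
  (3 for the all-model set, 5 for the double-pathology set in the original
  design).  Clusters are renumbered by descending size so labels are
  stable.
* **Exclusive DEPs**: proteins significant in the double-pathology model at
  the early (4 mo) or late (10 mo) contrast whose fold change stays below
  1.25 (symmetrically) in every single-pathology model at the same age.
* **Enrichment**: one-sided Fisher's exact (hypergeometric upper-tail)
  over-representation of a symbol list against gene sets from a GMT file,
  filtered at raw p < 0.01.  The background universe is the quantified
  proteome, not the genome: only quantified proteins can enter a
  foreground.  BH adjustment across terms is available but off by default,
  matching the raw-p filtering convention of the classic GO tools.
* **Bridge analysis**: given a PPI edge list (e.g. a STRING export) and two
  anchor proteins (App and Mapt — the amyloid and tau axes), bridge nodes
  are all non-anchor proteins on at least one simple anchor-to-anchor path
  of ≤ 3 edges.  The length cap matches the topology of interest (one or
  two intermediates); it is a flag.

## Synthetic-data generator

The generator exists so that every downstream stage is testable without
any external download, at the exact design of the study.  It emulates:

* 36 samples over four 10-plex sets, pooled channel 131, two runs per set,
  spike-in in every channel;
* a lognormal protein abundance distribution spanning ~6 orders of
  magnitude (log10 sd 1.0 around 1e5);
* planted differential archetypes: 15% of proteins are DEPs
  (85% gradually up-, 15% gradually down-regulated), with the log2 effect
  ramping linearly over 4 → 7 → 10 months up to `max_log2_effect = 1`.
  Effects apply fully to the amyloid-bearing genotypes (APP_PS1 and APT),
  attenuated by `tau_effect_scale = 0.1` in the tau-only genotype (which
  is therefore near-null, as in the original models), and never to WT.
  Archetype assignment uses exact quotas, so fixture counts are
  deterministic;
* four multiplicative lognormal noise levels (parameters are sds of the
  log multiplier): biological replicate scatter (0.10), per-measurement
  acquisition noise (0.07), per-(set, channel) loading error (0.09, shared
  by a set's two runs because the mixture is assembled once), a scalar
  per-set batch scale (0.062), and a per-(protein, set) batch effect
  (0.12) capturing protein-specific digestion/labeling differences between
  sets.  The spike-in, a purified standard added per channel, sees the
  scalar noise terms but not the protein-level batch term;
* missing reporter ions, completely at random per (protein, set, run,
  channel) at rate 0.09, plus planted metadata degradation (0.75%
  medium-confidence, 0.1% zero-unique-peptide proteins).

### Calibration of the defaults

The defaults are anchored to the published statistics of the study design
wherever one exists, chosen once:

* the spike-in CV across the 8 MS runs centers at **6.3%** (median 6.34
  over 150 simulations).  This statistic pins mainly the set-level scale
  (channel and acquisition noise enter divided by 10 through the
  run-mean), leaving the partition across components free;
* the remaining partition was fixed so that the qualitative noise
  hierarchy holds — duplicate-run agreement (R² ≈ 0.998) exceeds
  between-set pooled-channel agreement (R² ≈ 0.993) exceeds within-group
  replicate correlation — and so that planted 2-fold effects at 10 months
  are detected by the dual-threshold t-test with sensitivity ≥ 0.9 at
  n = 3 replicates;
* the missingness rate reproduces the published identification cascade:
  with per-run MCAR at 0.09, a merged cell is missing with probability
  0.09² and a protein is complete in all 40 merged designed channels with
  probability ≈ 0.72, matching the ~28% all-channel loss of the original
  cascade; the metadata-degradation rates match its two later stages.

### What the generator does not model

Co-isolation interference and ratio compression, peptide-to-protein
roll-up, isotope-impurity correction, informative (abundance-dependent)
missingness, and protein-protein abundance correlation.  Passing tests
therefore demonstrate correctness of the estimators and statistics under
the multiplicative-lognormal model, not robustness to those phenomena.

### Known statistical properties the tests expose

Two design-inherent effects show up in the acceptance suite and are worth
understanding rather than suppressing:

* **Mild conservatism of the t-test on pooled ratios.**  The pooled
  channel's acquisition noise is shared by all samples of a set; when
  transgenic and WT replicates co-locate in sets, that noise partially
  cancels in the group difference while still inflating the pooled
  variance estimate.  At the default noise the realized null rejection
  rate at α = 0.05 is ≈ 0.035 instead of 0.050 (exactly 0.050 when
  technical noise is switched off).  This is a property of any
  ratio-to-pooled TMT analysis with plain two-sample tests, not of this
  implementation.
* **Dispersion of the spike-in CV estimate.**  With only 8 run-level
  observations, the sample CV is a ~7-degree-of-freedom chi-type
  estimator with a relative spread of ~27%; individual experiments
  therefore scatter widely (roughly 3–10%) around the calibrated 6.3%
  center even though the center itself is accurate.

## Numerical choices

* Lognormal noise everywhere: intensities are positive and ratio
  distributions are near-normal, matching the field's standard model.
* Constant rows are detected by an exact range test (`max == min`) before
  z-normalization, because the floating-point sample sd of a constant row
  can round to ~1e-16 rather than 0.
* All correlations are computed on log10 intensities, making QC metrics
  exactly invariant to global rescaling of a run; pooled profiles are
  averaged across runs in log space (geometric mean) over complete-case
  proteins for the same reason.
* Clustering is deterministic for a fixed row order (scipy's linkage
  breaks ties by merging the lower-index pair first); cluster labels are
  renumbered by descending size.
* BH adjustment is the textbook step-up (`min_{j>=i} p_(j) m / j`,
  clipped at 1) in vectorized form; it is cross-checked in the tests
  against a brute-force implementation of the definition and against
  statsmodels.
* Degenerate inputs have defined behavior: zero variance in both t-test
  groups with equal means reports p = 1; all-identical ANOVA rows report
  F = 0; empty matrices and missing design cells raise errors naming the
  offending protein, set, or age.
* All randomness flows from one integer seed through numpy's PCG64;
  the ground-truth and experiment stages draw from independent spawned
  streams, so identical parameters give byte-identical tables.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on synthetic data:
the acceptance script simulates 2000 protein groups at the full 36-sample
design; the Monte-Carlo calibration checks use 200 seeds at 1000–2000
proteins; noiseless-oracle and cluster-recovery checks use 300–500
proteins.  These sizes give Monte-Carlo standard errors well below the
tolerances being checked while keeping a full run in the minutes range on
one CPU.

## Limitations

* The t-test/ANOVA machinery treats samples as independent; see the
  conservatism note above.
* Enrichment supports over-representation only (no depletion, no
  ranked-list statistics).
* The bridge definition enumerates simple paths, which is exponential in
  `max_len`; it is intended for the short caps (≤ 4) that the biological
  question implies.
* Sample-to-set assignment of the original experiment is not public; the
  default layout round-robins samples over sets, and any other layout can
  be supplied as a design file.
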