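"""Spike-in normalization, duplicate merging, quantifiability filters, ratios.

The quantification chain mirrors the study workflow:

1. :func:`spikein_normalize` — rescale every (set, run, channel) so the
   spike-in standard (ovalbumin) is equal everywhere, removing loading and
   acquisition scale differences.
2. :func:`merge_technical_duplicates` — average the two MS runs of each set.
3. :func:`filter_quantifiable` — keep protein groups quantified in all
   designed channels, with high identification confidence and at least one
   unique peptide, reporting the sequential cascade counts.
4. :func:`compute_normalized_abundance` — divide each sample channel by its
   set's pooled-reference channel ("normalized protein abundance"), which
   cancels any residual protein-independent per-set scale and bridges the
   four TMT batches.
5. :func:`compute_fold_change` — transgenic vs age-matched wild-type ratio
   of replicate means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .datatypes import ExperimentDesign, ReporterIntensityTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterReport:
    """Sequential counts of the quantifiability cascade."""

    n_identified: int
    n_all_channels: int
    n_high_confidence: int
    n_unique_peptide: int

    def __post_init__(self) -> None:
        counts = (self.n_identified, self.n_all_channels,
                  self.n_high_confidence, self.n_unique_peptide)
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValidationError(f"filter counts must be non-increasing: {counts}")


def _designed_columns(table: ReporterIntensityTable, design: ExperimentDesign) -> list:
    """Intensity columns that carry a sample or the pooled reference."""
    cols = []
    for set_id, run_id, channel in table.intensities.columns:
        if (set_id, channel) in design.assignments or \
                design.pooled_channel.get(set_id) == channel:
            cols.append((set_id, run_id, channel))
    return cols


def spikein_normalize(
    table: ReporterIntensityTable, design: ExperimentDesign
) -> ReporterIntensityTable:
    """Rescale channels so the spike-in standard is equal in all of them.

    Each designed (set, run, channel) is multiplied by ``reference /
    spike-in`` where the reference is the geometric mean of the spike-in
    intensity over all designed columns — a symmetric choice that makes the
    operation idempotent and channel-order independent.

    Raises
    ------
    ValidationError
        If the spike-in accession is absent, or its intensity is missing or
        zero in any designed column (named in the message).
    """
    acc = design.spikein_accession
    if acc not in table.accessions:
        raise ValidationError(f"spike-in accession {acc!r} not in table")
    cols = _designed_columns(table, design)
    spike = table.intensities.loc[acc, cols]
    bad = spike.index[spike.isna() | (spike <= 0)]
    if len(bad):
        s, r, c = bad[0]
        raise ValidationError(
            f"spike-in {acc} missing or zero in set{s}.run{r}.{c}"
        )
    reference = float(np.exp(np.log(spike.to_numpy(dtype=float)).mean()))
    factors = reference / spike
    out = table.intensities.copy()
    out.loc[:, cols] = out.loc[:, cols].mul(factors, axis=1)
    return ReporterIntensityTable(records=table.records.copy(), intensities=out)


def merge_technical_duplicates(table: ReporterIntensityTable) -> ReporterIntensityTable:
    """Collapse technical runs: mean of non-missing values per (set, channel).

    A value is missing in the output only if it was missing in every run.
    The merged table carries a single run (id 1) per set.
    """
    from .datatypes import TMT10_CHANNELS

    merged = table.intensities.T.groupby(level=["set", "channel"]).mean().T
    merged.columns = pd.MultiIndex.from_tuples(
        [(s, 1, c) for s, c in merged.columns], names=["set", "run", "channel"]
    )
    merged = merged[sorted(merged.columns,
                           key=lambda c: (c[0], c[1], TMT10_CHANNELS.index(c[2])))]
    return ReporterIntensityTable(records=table.records.copy(), intensities=merged)


def filter_quantifiable(
    table: ReporterIntensityTable, design: ExperimentDesign
) -> tuple[ReporterIntensityTable, FilterReport]:
    """Apply the quantifiability cascade in its canonical order.

    Sequentially keeps proteins (i) quantified (non-missing) in every
    designed channel of every set, (ii) at high identification confidence,
    (iii) with >= 1 unique peptide, and reports the count after each stage.
    """
    n_identified = len(table.accessions)
    cols = _designed_columns(table, design)
    complete = table.intensities[cols].notna().all(axis=1)
    stage1 = table.records.index[complete]
    high = table.records.loc[stage1, "confidence"] == "high"
    stage2 = stage1[high]
    unique = table.records.loc[stage2, "unique_peptides"] >= 1
    stage3 = stage2[unique]
    report = FilterReport(
        n_identified=n_identified,
        n_all_channels=int(len(stage1)),
        n_high_confidence=int(len(stage2)),
        n_unique_peptide=int(len(stage3)),
    )
    logger.info(
        "quantifiability cascade: %d identified -> %d all-channel -> "
        "%d high-confidence -> %d unique-peptide",
        *(report.n_identified, report.n_all_channels,
          report.n_high_confidence, report.n_unique_peptide),
    )
    return table.subset(stage3), report


def compute_normalized_abundance(
    table: ReporterIntensityTable, design: ExperimentDesign
) -> pd.DataFrame:
    """Per-protein ratio of each sample channel to its set's pooled channel.

    Expects a merged (single-run), filtered table.  The pooled channels and
    the spike-in standard are excluded from the output, whose columns are a
    ``(genotype, age_months, replicate)`` MultiIndex in design order.

    Raises
    ------
    ValidationError
        If the table still has multiple runs, contains missing values in
        designed channels, or a pooled intensity is zero (protein and set
        named in the message).
    """
    for set_id in table.sets:
        if len(table.runs(set_id)) != 1:
            raise ValidationError(
                f"set {set_id} has multiple runs; merge technical duplicates first"
            )
    keep = table.accessions.drop(design.spikein_accession,
                                 errors="ignore")
    if len(keep) == 0:
        raise ValidationError("empty matrix: no proteins left to normalize")
    cols = _designed_columns(table, design)
    block = table.intensities.loc[keep, cols]
    if block.isna().to_numpy().any():
        raise ValidationError(
            "missing values among designed channels; apply filter_quantifiable first"
        )

    def pooled_column(set_id: int) -> pd.Series:
        run_id = table.runs(set_id)[0]
        pooled = table.intensities.loc[keep, (set_id, run_id, design.pooled_channel[set_id])]
        zero = pooled.index[pooled == 0]
        if len(zero):
            raise ValidationError(
                f"pooled-channel intensity is zero for {zero[0]} in set {set_id}"
            )
        return pooled

    pooled_by_set = {s: pooled_column(s) for s in design.sets}
    from .datatypes import GENOTYPES

    ordered = sorted(
        design.samples,
        key=lambda s: (GENOTYPES.index(s.genotype), s.age_months, s.replicate),
    )
    data = {}
    for label in ordered:
        set_id, channel = design.channel_of(label)
        run_id = table.runs(set_id)[0]
        data[(label.genotype, label.age_months, label.replicate)] = (
            table.intensities.loc[keep, (set_id, run_id, channel)] / pooled_by_set[set_id]
        )
    matrix = pd.DataFrame(data)
    matrix.columns.names = ["genotype", "age_months", "replicate"]
    matrix.index.name = "accession"
    return matrix


def group_block(matrix: pd.DataFrame, genotype: str, age_months: int) -> pd.DataFrame:
    """Replicate columns of one (genotype, age) group of an abundance matrix."""
    cols = [c for c in matrix.columns if c[0] == genotype and c[1] == age_months]
    return matrix[cols]


def compute_fold_change(
    matrix: pd.DataFrame,
    design: ExperimentDesign | None = None,
    method: str = "ratio_of_means",
) -> pd.DataFrame:
    """Transgenic vs age-matched wild-type fold change per (genotype, age).

    ``ratio_of_means`` (default) divides the transgenic replicate mean by the
    WT replicate mean, which is stable under unequal replicate counts;
    ``mean_of_ratios`` averages per-replicate-index ratios instead.  The
    grouping comes from the matrix's own sample columns; ``design`` is
    accepted for interface symmetry with the other stages.
    """
    if method not in ("ratio_of_means", "mean_of_ratios"):
        raise ValidationError(f"unknown fold-change method {method!r}")
    genotypes = sorted({g for g, _, _ in matrix.columns if g != "WT"},
                       key=["APP_PS1", "Tau", "APT"].index)
    ages = sorted({a for _, a, _ in matrix.columns})
    for age in ages:
        if not any(g == "WT" and a == age for g, a, _ in matrix.columns):
            raise ValidationError(f"no wild-type samples at {age} months")
    data = {}
    for genotype in genotypes:
        for age in ages:
            tg = group_block(matrix, genotype, age)
            if tg.shape[1] == 0:
                continue
            wt = group_block(matrix, "WT", age)
            if method == "ratio_of_means":
                data[(genotype, age)] = tg.mean(axis=1) / wt.mean(axis=1)
            else:
                n = min(tg.shape[1], wt.shape[1])
                ratios = tg.iloc[:, :n].to_numpy() / wt.iloc[:, :n].to_numpy()
                data[(genotype, age)] = pd.Series(ratios.mean(axis=1), index=matrix.index)
    fc = pd.DataFrame(data)
    fc.columns.names = ["genotype", "age_months"]
    fc.index.name = "accession"
    return fc
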