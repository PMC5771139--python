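"""Quality-assessment statistics for a multi-set TMT experiment.

Four statistics summarise the noise hierarchy of the design, from purely
technical to biological:

* spike-in CV across repeated MS runs (acquisition repeatability),
* R^2 between the technical duplicate runs of each set,
* R^2 between the pooled-reference profiles of different sets (batch
  agreement — the pooled channel is the same mixture in every set),
* mean pairwise Pearson correlation among biological replicates.

All correlations are computed on log10 intensities, which makes them
invariant to any global multiplicative rescaling of a run.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .datatypes import ExperimentDesign, ReporterIntensityTable

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    spikein_cv_percent: float
    duplicate_r2: dict[int, float] = field(default_factory=dict)
    set_to_set_r2: dict[tuple[int, int], float] = field(default_factory=dict)
    replicate_pearson: dict[tuple[str, int], float] = field(default_factory=dict)

    @property
    def duplicate_r2_mean(self) -> float:
        return float(np.mean(list(self.duplicate_r2.values())))

    @property
    def set_to_set_r2_mean(self) -> float:
        return float(np.mean(list(self.set_to_set_r2.values())))

    @property
    def replicate_pearson_mean(self) -> float:
        return float(np.mean(list(self.replicate_pearson.values())))

    def to_frame(self) -> pd.DataFrame:
        rows = [("spikein_cv_percent", "all", self.spikein_cv_percent)]
        rows += [("duplicate_r2", f"set{s}", v) for s, v in sorted(self.duplicate_r2.items())]
        rows += [("duplicate_r2", "mean", self.duplicate_r2_mean)]
        rows += [("set_to_set_r2", f"set{a}-set{b}", v)
                 for (a, b), v in sorted(self.set_to_set_r2.items())]
        rows += [("set_to_set_r2", "mean", self.set_to_set_r2_mean)]
        rows += [("replicate_pearson", f"{g}.{a}", v)
                 for (g, a), v in sorted(self.replicate_pearson.items())]
        rows += [("replicate_pearson", "mean", self.replicate_pearson_mean)]
        return pd.DataFrame(rows, columns=["metric", "unit", "value"])


def _paired_log10(x: pd.Series, y: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    ok = x.notna() & y.notna() & (x > 0) & (y > 0)
    return np.log10(x[ok].to_numpy(dtype=float)), np.log10(y[ok].to_numpy(dtype=float))


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """R^2 of the least-squares linear fit of y on x (= squared Pearson r)."""
    if len(x) < 2:
        raise ValidationError("fewer than 2 shared observations for correlation")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def spikein_cv(table: ReporterIntensityTable, design: ExperimentDesign) -> float:
    """Spike-in coefficient of variation (%) across repeated MS runs.

    One observation per (set, run): that run's mean spike-in intensity over
    its designed channels.  CV = 100 x sample sd (n-1 denominator) / mean.
    Computed on the un-normalized table — spike-in normalization would make
    it zero by construction.
    """
    acc = design.spikein_accession
    if acc not in table.accessions:
        raise ValidationError(f"spike-in accession {acc!r} not in table")
    observations = []
    for set_id in table.sets:
        for run_id in table.runs(set_id):
            cols = [
                (s, r, c) for (s, r, c) in table.intensities.columns
                if s == set_id and r == run_id
                and ((s, c) in design.assignments or design.pooled_channel.get(s) == c)
            ]
            values = table.intensities.loc[acc, cols].dropna()
            if len(values):
                observations.append(float(values.mean()))
    if len(observations) < 2:
        raise ValidationError("spike-in CV needs >= 2 (set, run) observations")
    obs = np.asarray(observations)
    return float(100.0 * obs.std(ddof=1) / obs.mean())


def duplicate_agreement(table: ReporterIntensityTable) -> dict[int, float]:
    """Per-set R^2 between log10 intensities of the two technical runs.

    Computed over all (protein, channel) pairs observed in both runs; sets
    with a single run are skipped with a logged notice.
    """
    out: dict[int, float] = {}
    for set_id in table.sets:
        runs = table.runs(set_id)
        if len(runs) < 2:
            logger.warning("set %d has a single run; duplicate R^2 skipped", set_id)
            continue
        r1, r2 = runs[:2]
        x = table.intensities.xs((set_id, r1), axis=1, level=["set", "run"]).stack()
        y = table.intensities.xs((set_id, r2), axis=1, level=["set", "run"]).stack()
        x, y = x.align(y, join="inner")
        lx, ly = _paired_log10(x, y)
        out[set_id] = _r2(lx, ly)
    return out


def pooled_channel_agreement(
    table: ReporterIntensityTable, design: ExperimentDesign
) -> dict[tuple[int, int], float]:
    """R^2 between pooled-reference profiles for every pair of sets.

    The pooled channel holds the same mixture in every set, so after log10
    transform the agreement across sets measures pure batch reproducibility.
    Run-level values are averaged per set in log space (geometric mean) over
    proteins observed in all of a set's runs, which keeps the metric exactly
    invariant to rescaling any single run.

    Raises
    ------
    ValidationError
        With < 2 sets, or < 2 shared quantified proteins for a pair.
    """
    sets = table.sets
    if len(sets) < 2:
        raise ValidationError("pooled-channel agreement needs >= 2 sets")
    profiles = {}
    for set_id in sets:
        channel = design.pooled_channel[set_id]
        cols = [(s, r, c) for (s, r, c) in table.intensities.columns
                if s == set_id and c == channel]
        block = table.intensities[cols]
        complete = block.notna().all(axis=1) & (block > 0).all(axis=1)
        profiles[set_id] = np.log10(block.where(complete)).mean(axis=1)
    out: dict[tuple[int, int], float] = {}
    for a, b in itertools.combinations(sets, 2):
        x, y = profiles[a], profiles[b]
        ok = x.notna() & y.notna()
        if ok.sum() < 2:
            raise ValidationError(f"sets {a} and {b} share fewer than 2 proteins")
        out[(a, b)] = _r2(x[ok].to_numpy(), y[ok].to_numpy())
    return out


def replicate_correlation(
    matrix: pd.DataFrame, design: ExperimentDesign | None = None
) -> dict[tuple[str, int], float]:
    """Mean pairwise Pearson r of log10 abundances within (genotype, age) groups.

    Groups with fewer than two replicates are skipped.  The design argument
    is accepted for interface symmetry; grouping comes from the matrix's own
    (genotype, age_months, replicate) columns.
    """
    out: dict[tuple[str, int], float] = {}
    groups: dict[tuple[str, int], list] = {}
    for col in matrix.columns:
        groups.setdefault((col[0], col[1]), []).append(col)
    for key, cols in groups.items():
        if len(cols) < 2:
            continue
        rs = []
        for ca, cb in itertools.combinations(cols, 2):
            lx, ly = _paired_log10(matrix[ca], matrix[cb])
            if len(lx) < 2:
                continue
            rs.append(float(np.corrcoef(lx, ly)[0, 1]))
        if rs:
            out[key] = float(np.mean(rs))
    return out


def compute_qc_report(
    raw_table: ReporterIntensityTable,
    matrix: pd.DataFrame,
    design: ExperimentDesign,
) -> QCReport:
    """All QC statistics in one pass (raw table for CV/R^2, matrix for replicates)."""
    return QCReport(
        spikein_cv_percent=spikein_cv(raw_table, design),
        duplicate_r2=duplicate_agreement(raw_table),
        set_to_set_r2=pooled_channel_agreement(raw_table, design),
        replicate_pearson=replicate_correlation(matrix, design),
    )
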