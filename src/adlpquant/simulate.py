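"""Synthetic reporter-ion data with the statistical structure the pipeline assumes.

The generator emulates the study design end-to-end: 36 hippocampal samples
(4 genotypes x 3 ages x 3 biological replicates) distributed over four
10-plex TMT sets, each set carrying a pooled-reference channel (131) built
from the equal-weight mean of all biological samples, an ovalbumin-like
spike-in at constant amount in every channel, two technical MS runs per set,
and multiplicative lognormal noise at four levels:

* biological replicate-to-replicate scatter (``biological_cv``),
* per-(set, channel) loading error (``channel_scale_sd``), shared by the two
  runs of a set because each 10-plex mixture is assembled once and injected
  twice,
* per-set batch scale (``set_scale_sd``) plus a per-(protein, set) batch
  effect (``batch_protein_sd``) capturing protein-specific digestion and
  labeling efficiency differences between sets — the component that makes
  batch agreement genuinely worse than run-to-run agreement,
* per-measurement acquisition noise (``technical_cv``).

The per-(protein, set) batch effect multiplies every channel of a set
equally, so pooled-reference division cancels it — which is exactly why the
pooled channel bridges batches.  The spike-in is a purified standard added
per channel late in preparation, so it sees the scalar set/channel/run
noise but not the protein-level batch term.

Differential proteins are planted as archetypes: gradually up- or
down-regulated in the amyloid-bearing genotypes (APP_PS1 and APT), with the
same effect attenuated by ``tau_effect_scale`` in the tau-only genotype and
absent in wild type.  Effects ramp linearly in log2 space over the ages
4 -> 7 -> 10 months up to ``max_log2_effect``.  Archetype assignment uses
exact quotas (``round(frac * n)``) so planted counts are deterministic.

All randomness flows from a single integer seed through numpy's PCG64
generator; identical parameters yield byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._errors import ValidationError
from .datatypes import (
    AGES,
    GENOTYPES,
    TMT10_CHANNELS,
    AnnotationSets,
    ExperimentDesign,
    ReporterIntensityTable,
)

ARCHETYPES = ("up_gradual", "down_gradual", "null")

#: log2-effect ramp across the three age points (fraction of the 10-month effect).
AGE_RAMP: dict[int, float] = {4: 1 / 3, 7: 2 / 3, 10: 1.0}

@dataclass
class SimulationParams:
    """Knobs of the synthetic experiment.

    All ``*_cv`` / ``*_sd`` parameters are the standard deviation of the
    natural log of a lognormal multiplier (numerically ~= the coefficient of
    variation for small values).  Defaults reproduce the study conditions:
    the filter-cascade loss rates match the published identification cascade,
    the DEP fraction and up:down split match the published ANOVA DEP counts,
    and the technical/channel/set noise is calibrated so the spike-in CV
    across the 8 MS runs centers at the published 6.3%.
    """

    n_proteins: int = 2000
    frac_dep: float = 0.15
    #: (up_gradual, down_gradual) split within the DEP fraction.
    archetype_mix: tuple[float, float] = (0.85, 0.15)
    max_log2_effect: float = 1.0
    tau_effect_scale: float = 0.1
    biological_cv: float = 0.10
    technical_cv: float = 0.07
    channel_scale_sd: float = 0.09
    set_scale_sd: float = 0.062
    batch_protein_sd: float = 0.12
    missing_rate: float = 0.09
    frac_low_confidence: float = 0.0075
    frac_zero_unique: float = 0.001
    seed: int = 0
    # shape of the abundance distribution (six orders of magnitude dynamic range)
    base_log10_sd: float = 1.0
    base_mean_intensity: float = 1.0e5
    spike_intensity: float = 5.0e5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be positive")
        for name in ("frac_dep", "biological_cv", "technical_cv", "missing_rate",
                     "frac_low_confidence", "frac_zero_unique", "tau_effect_scale"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")
        up, down = self.archetype_mix
        if up < 0 or down < 0 or abs(up + down - 1.0) > 1e-9:
            raise ValidationError("archetype_mix proportions must be >=0 and sum to 1")
        if self.max_log2_effect <= 0:
            raise ValidationError("max_log2_effect must be positive")
        for name in ("channel_scale_sd", "set_scale_sd", "batch_protein_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """Planted state of a simulated experiment, the oracle for every test.

    ``true_means`` holds the noise-free mean abundance per protein and
    (genotype, age) cell; null-archetype proteins are identical across
    genotypes at every age by construction.
    """

    accessions: pd.Index
    gene_symbols: pd.Series
    archetype: pd.Series
    base_abundance: pd.Series
    true_means: pd.DataFrame  # columns: MultiIndex (genotype, age_months)
    confidence: pd.Series
    unique_peptides: pd.Series

    @property
    def dep_accessions(self) -> pd.Index:
        return self.accessions[self.archetype != "null"]

    def expected_fold_change(self, genotype: str, age_months: int) -> pd.Series:
        """Planted transgenic / age-matched WT fold change."""
        return self.true_means[(genotype, age_months)] / self.true_means[("WT", age_months)]


def _rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    truth_ss, expt_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(truth_ss), np.random.default_rng(expt_ss)


def generate_ground_truth(params: SimulationParams) -> GroundTruth:
    """Plant per-protein archetypes, abundances, and identification metadata.

    Archetype counts use exact quotas: ``n_dep = round(frac_dep * n)`` split
    ``round(n_dep * mix)`` up / remainder down, assigned to a seeded random
    permutation of proteins, so counts are deterministic for fixed parameters.
    """
    rng, _ = _rngs(params.seed)
    n = params.n_proteins
    accessions = pd.Index([f"P{i:06d}" for i in range(1, n + 1)], name="accession")
    symbols = pd.Series([f"gene{i:05d}" for i in range(1, n + 1)], index=accessions,
                        name="gene_symbol")

    base = pd.Series(
        params.base_mean_intensity
        * 10.0 ** rng.normal(0.0, params.base_log10_sd, size=n),
        index=accessions, name="base_abundance",
    )

    n_dep = round(params.frac_dep * n)
    n_up = round(n_dep * params.archetype_mix[0])
    n_down = n_dep - n_up
    order = rng.permutation(n)
    archetype = np.full(n, "null", dtype=object)
    archetype[order[:n_up]] = "up_gradual"
    archetype[order[n_up:n_up + n_down]] = "down_gradual"
    archetype = pd.Series(archetype, index=accessions, name="archetype")

    sign = archetype.map({"up_gradual": 1.0, "down_gradual": -1.0, "null": 0.0}).to_numpy()
    genotype_scale = {"WT": 0.0, "APP_PS1": 1.0, "APT": 1.0, "Tau": params.tau_effect_scale}
    cols = pd.MultiIndex.from_product([GENOTYPES, AGES], names=["genotype", "age_months"])
    means = np.empty((n, len(cols)))
    for j, (genotype, age) in enumerate(cols):
        log2_effect = sign * params.max_log2_effect * AGE_RAMP[age] * genotype_scale[genotype]
        means[:, j] = base.to_numpy() * 2.0 ** log2_effect
    true_means = pd.DataFrame(means, index=accessions, columns=cols)

    confidence = pd.Series("high", index=accessions, name="confidence", dtype=object)
    n_low = round(params.frac_low_confidence * n)
    confidence.iloc[rng.permutation(n)[:n_low]] = "medium"

    unique_peptides = pd.Series(
        1 + rng.poisson(7.0, size=n), index=accessions, name="unique_peptides"
    )
    n_zero = round(params.frac_zero_unique * n)
    unique_peptides.iloc[rng.permutation(n)[:n_zero]] = 0

    return GroundTruth(
        accessions=accessions,
        gene_symbols=symbols,
        archetype=archetype,
        base_abundance=base,
        true_means=true_means,
        confidence=confidence,
        unique_peptides=unique_peptides,
    )


def simulate_experiment(
    truth: GroundTruth,
    design: ExperimentDesign,
    params: SimulationParams,
    n_runs: int = 2,
) -> ReporterIntensityTable:
    """Render a ground truth into a raw reporter-ion intensity table.

    Each intensity is ``signal x set-scale x channel-scale x run-noise``
    where the signal is the planted mean times a biological replicate effect
    for sample channels, the equal-weight mean of all samples' signal for the
    pooled channel, and a constant for the spike-in (which sees only the
    technical noise levels, never biology).  Missing reporter ions and
    degraded identification metadata are planted at the configured rates;
    the spike-in row is never masked (its absence would be a failed
    experiment, not a missing value).
    """
    _, rng = _rngs(params.seed)
    samples = design.samples
    for label in samples:
        if (label.genotype, label.age_months) not in truth.true_means.columns:
            raise ValidationError(
                f"design references ({label.genotype}, {label.age_months}) "
                "absent from the ground truth"
            )
    n = len(truth.accessions)
    n_samples = len(samples)

    # biological replicate effects, one multiplier per (protein, sample)
    bio = np.exp(rng.normal(0.0, params.biological_cv, size=(n, n_samples)))
    sample_mean = np.column_stack(
        [truth.true_means[(s.genotype, s.age_months)].to_numpy() for s in samples]
    )
    signal = sample_mean * bio
    pool = signal.mean(axis=1)  # the pooled reference mixes all samples equally

    sets = design.sets
    runs = list(range(1, n_runs + 1))
    set_mult = {s: np.exp(rng.normal(0.0, params.set_scale_sd)) for s in sets}
    chan_mult = {
        (s, c): np.exp(rng.normal(0.0, params.channel_scale_sd))
        for s in sets for c in TMT10_CHANNELS
    }
    # protein-specific batch effect, constant over a set's channels and runs
    batch = {
        s: np.exp(rng.normal(0.0, params.batch_protein_sd, size=n)) for s in sets
    }

    columns = pd.MultiIndex.from_tuples(
        [(s, r, c) for s in sets for r in runs for c in TMT10_CHANNELS],
        names=["set", "run", "channel"],
    )
    sample_for_channel = {key: samples.index(lbl) for key, lbl in design.assignments.items()}

    n_rows = n + 1  # endogenous proteins + spike-in
    values = np.full((n_rows, len(columns)), np.nan)
    designed = np.zeros(len(columns), dtype=bool)
    tech = np.exp(rng.normal(0.0, params.technical_cv, size=(n_rows, len(columns))))
    for j, (set_id, _run, channel) in enumerate(columns):
        scale = set_mult[set_id] * chan_mult[(set_id, channel)]
        if (set_id, channel) in sample_for_channel:
            col_signal = signal[:, sample_for_channel[(set_id, channel)]]
        elif design.pooled_channel.get(set_id) == channel:
            col_signal = pool
        else:
            continue  # channel not used by this (reduced) design
        designed[j] = True
        values[:n, j] = col_signal * batch[set_id] * scale * tech[:n, j]
        values[n, j] = params.spike_intensity * scale * tech[n, j]

    if params.missing_rate > 0:
        mask = rng.random(size=(n, len(columns))) < params.missing_rate
        mask[:, ~designed] = False
        values[:n][mask] = np.nan

    accessions = truth.accessions.append(
        pd.Index([design.spikein_accession])
    ).rename("accession")
    records = pd.DataFrame(
        {
            "gene_symbol": list(truth.gene_symbols) + ["ova_spike"],
            "confidence": list(truth.confidence) + ["high"],
            "unique_peptides": list(truth.unique_peptides) + [20],
            "description": ["synthetic protein group"] * n + ["spike-in standard"],
        },
        index=accessions,
    )
    intensities = pd.DataFrame(values, index=accessions, columns=columns)
    return ReporterIntensityTable(records=records, intensities=intensities)


def simulate_dataset(
    params: SimulationParams, design: ExperimentDesign | None = None
) -> tuple[ReporterIntensityTable, ExperimentDesign, GroundTruth]:
    """One-call convenience: ground truth + raw table under the study design."""
    if design is None:
        design = ExperimentDesign.default()
    truth = generate_ground_truth(params)
    table = simulate_experiment(truth, design, params)
    return table, design, truth


# ---------------------------------------------------------------------------
# annotation / PPI plumbing for download-free end-to-end runs
# ---------------------------------------------------------------------------

def simulate_annotation_sets(
    symbols: Sequence[str],
    n_terms: int = 40,
    size_range: tuple[int, int] = (10, 80),
    seed: int = 0,
    planted: Mapping[str, Iterable[str]] | None = None,
) -> AnnotationSets:
    """Random gene sets over a symbol universe, optionally with planted terms.

    ``planted`` maps a term id to an explicit member list (e.g. genes of one
    simulated archetype) so enrichment has a known positive control.
    """
    rng = np.random.default_rng(seed)
    sets: dict[str, tuple[str, Iterable[str]]] = {}
    lo, hi = size_range
    hi = min(hi, len(symbols))
    for i in range(1, n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(symbols), size=size, replace=False)
        sets[f"SYN:{i:04d}"] = (f"synthetic term {i}", [symbols[j] for j in members])
    for term, members in (planted or {}).items():
        sets[term] = (term, list(members))
    return AnnotationSets.from_members(sets)


def simulate_ppi_graph(
    symbols: Sequence[str],
    anchors: tuple[str, str] = ("App", "Mapt"),
    bridge_symbols: Sequence[str] = (),
    n_random_edges: int = 200,
    seed: int = 0,
    score_range: tuple[float, float] = (0.4, 0.999),
) -> nx.Graph:
    """Random undirected PPI graph with planted anchor-to-anchor bridges.

    Every symbol in ``bridge_symbols`` receives one edge to each anchor, so
    the anchors are connected through known length-2 paths; the remaining
    edges are drawn uniformly over symbol pairs.  Scores are uniform in
    ``score_range``.  Symbols are stored lower-cased (case-insensitive match).
    """
    rng = np.random.default_rng(seed)
    norm = AnnotationSets.normalize
    graph = nx.Graph()
    a, b = norm(anchors[0]), norm(anchors[1])
    graph.add_nodes_from([a, b])
    lo, hi = score_range
    for s in bridge_symbols:
        s = norm(s)
        graph.add_edge(a, s, score=float(rng.uniform(lo, hi)))
        graph.add_edge(s, b, score=float(rng.uniform(lo, hi)))
    pool = [norm(s) for s in symbols]
    for _ in range(n_random_edges):
        i, j = rng.integers(0, len(pool), size=2)
        if pool[i] == pool[j]:
            continue
        graph.add_edge(pool[i], pool[j], score=float(rng.uniform(lo, hi)))
    return graph
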