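"""Shared domain types for the TMT reporter-ion quantification pipeline.

The quantification unit throughout is the *protein group*: a set of proteins
indistinguishable by their identified peptides, carried as one row keyed by a
unique accession.  Reporter-ion intensities are organised per TMT set (one
10-plex mixture), per technical MS run (each mixture is injected twice), and
per reporter channel (TMT 10-plex nomenclature 126 ... 131).  One channel per
set holds the pooled reference sample; dividing by it bridges quantification
across sets.

Matrices downstream of normalization are plain :class:`pandas.DataFrame`
objects: proteins on the index, samples (``genotype``, ``age_months``,
``replicate`` MultiIndex) on the columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._errors import ValidationError

#: Reporter channels of a TMT 10-plex kit, in mass order.
TMT10_CHANNELS: tuple[str, ...] = (
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131",
)

#: Genotypes of the four-model cross (wild type, amyloid-only, tau-only, both).
GENOTYPES: tuple[str, ...] = ("WT", "APP_PS1", "Tau", "APT")

#: Age points (months) of the longitudinal design.
AGES: tuple[int, ...] = (4, 7, 10)

CONFIDENCE_LEVELS: tuple[str, ...] = ("high", "medium", "low")

#: Names of the protein metadata columns, in on-disk order.
METADATA_COLUMNS: tuple[str, ...] = (
    "gene_symbol", "confidence", "unique_peptides", "description",
)


@dataclass(frozen=True, order=True)
class SampleLabel:
    """One biological sample: a genotype x age x replicate cell."""

    genotype: str
    age_months: int
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"unknown genotype {self.genotype!r}")
        if self.age_months not in AGES:
            raise ValidationError(f"unsupported age {self.age_months!r} months")
        if self.replicate < 1:
            raise ValidationError("replicate index must be >= 1")

    def __str__(self) -> str:  # "APT.10.r2"
        return f"{self.genotype}.{self.age_months}.r{self.replicate}"

    @classmethod
    def parse(cls, text: str) -> "SampleLabel":
        try:
            genotype, age, rep = text.split(".")
            return cls(genotype, int(age), int(rep.lstrip("r")))
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"cannot parse sample label {text!r}") from exc


@dataclass
class ExperimentDesign:
    """Channel-to-sample map for a multi-set TMT experiment.

    Parameters
    ----------
    assignments
        ``(set_id, channel)`` -> :class:`SampleLabel` for biological sample
        channels only.  The pooled reference channel of each set is recorded
        separately in ``pooled_channel``.
    pooled_channel
        ``set_id`` -> channel carrying the pooled reference (defaults to
        channel 131 in the study design).
    spikein_accession
        Accession of the spike-in standard (ovalbumin in the study) present
        at constant amount in every channel.
    """

    assignments: dict[tuple[int, str], SampleLabel]
    pooled_channel: dict[int, str]
    spikein_accession: str = "OVALBUMIN_SPIKE"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: dict[SampleLabel, tuple[int, str]] = {}
        for (set_id, channel), label in self.assignments.items():
            if channel not in TMT10_CHANNELS:
                raise ValidationError(
                    f"channel {channel!r} in set {set_id} is not a TMT 10-plex channel"
                )
            if label in seen:
                raise ValidationError(f"sample label {label} assigned twice")
            seen[label] = (set_id, channel)
        for set_id in self.sets:
            if set_id not in self.pooled_channel:
                raise ValidationError(f"set {set_id} has no pooled reference channel")
        for set_id, channel in self.pooled_channel.items():
            if channel not in TMT10_CHANNELS:
                raise ValidationError(
                    f"pooled channel {channel!r} of set {set_id} is not a TMT channel"
                )
            if (set_id, channel) in self.assignments:
                raise ValidationError(
                    f"pooled channel {channel} of set {set_id} also assigned to a sample"
                )
        if not self.spikein_accession:
            raise ValidationError("spike-in accession must be non-empty")

    @property
    def sets(self) -> list[int]:
        ids = {s for s, _ in self.assignments} | set(self.pooled_channel)
        return sorted(ids)

    @property
    def samples(self) -> list[SampleLabel]:
        """All sample labels, ordered by (set, channel position)."""
        def key(item: tuple[tuple[int, str], SampleLabel]):
            (set_id, channel), _ = item
            return (set_id, TMT10_CHANNELS.index(channel))

        return [label for _, label in sorted(self.assignments.items(), key=key)]

    def channel_of(self, label: SampleLabel) -> tuple[int, str]:
        for key, value in self.assignments.items():
            if value == label:
                return key
        raise KeyError(label)

    def groups(self) -> dict[tuple[str, int], list[SampleLabel]]:
        """Sample labels keyed by (genotype, age) group."""
        out: dict[tuple[str, int], list[SampleLabel]] = {}
        for label in self.samples:
            out.setdefault((label.genotype, label.age_months), []).append(label)
        for labels in out.values():
            labels.sort()
        return out

    @classmethod
    def default(
        cls,
        genotypes: Iterable[str] = GENOTYPES,
        ages: Iterable[int] = AGES,
        n_replicates: int = 3,
        n_sets: int = 4,
        pooled_channel: str = "131",
        spikein_accession: str = "OVALBUMIN_SPIKE",
    ) -> "ExperimentDesign":
        """The study layout: 36 samples round-robined over four 10-plex sets.

        Nine sample channels plus one pooled reference channel per set.  The
        sample-to-set assignment of the original experiment is not public, so
        samples are distributed round-robin in (genotype, age, replicate)
        order, which balances every set; any other layout can be supplied via
        an explicit design file.
        """
        labels = [
            SampleLabel(g, a, r)
            for g in genotypes
            for a in ages
            for r in range(1, n_replicates + 1)
        ]
        sample_channels = [c for c in TMT10_CHANNELS if c != pooled_channel]
        per_set = {s: 0 for s in range(1, n_sets + 1)}
        assignments: dict[tuple[int, str], SampleLabel] = {}
        for i, label in enumerate(labels):
            set_id = (i % n_sets) + 1
            slot = per_set[set_id]
            if slot >= len(sample_channels):
                raise ValidationError(
                    f"design does not fit: set {set_id} would need >"
                    f"{len(sample_channels)} sample channels"
                )
            assignments[(set_id, sample_channels[slot])] = label
            per_set[set_id] = slot + 1
        return cls(
            assignments=assignments,
            pooled_channel={s: pooled_channel for s in range(1, n_sets + 1)},
            spikein_accession=spikein_accession,
        )


@dataclass
class ReporterIntensityTable:
    """Raw (or normalized) reporter-ion intensities plus identification metadata.

    Attributes
    ----------
    records
        Protein-group metadata indexed by accession with columns
        ``gene_symbol``, ``confidence``, ``unique_peptides``, ``description``.
    intensities
        Accession-indexed frame whose columns are a ``(set, run, channel)``
        MultiIndex.  ``NaN`` encodes a missing reporter ion and is distinct
        from an observed zero.
    """

    records: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.records.index.has_duplicates:
            dupes = self.records.index[self.records.index.duplicated()].tolist()
            raise ValidationError(f"duplicate accessions: {dupes[:5]}")
        if (self.records.index == "").any():
            raise ValidationError("empty accession")
        if not self.records.index.equals(self.intensities.index):
            raise ValidationError("records and intensities index mismatch")
        if list(self.intensities.columns.names) != ["set", "run", "channel"]:
            raise ValidationError("intensity columns must be a (set, run, channel) index")
        for set_id in self.sets:
            for run_id in self.runs(set_id):
                if run_id not in (1, 2):
                    raise ValidationError(
                        f"run id {run_id} in set {set_id}: only technical "
                        "duplicates (runs 1 and 2) are supported"
                    )
                channels = self.channels(set_id, run_id)
                if len(channels) != 10:
                    raise ValidationError(
                        f"set {set_id} run {run_id} has {len(channels)} channels, "
                        "expected the 10 channels of a 10-plex set"
                    )
        values = self.intensities.to_numpy(dtype=float)
        if np.nanmin(values, initial=np.inf) < 0:
            bad = self.intensities.lt(0).any(axis=1)
            acc = self.records.index[bad][0]
            col = self.intensities.columns[self.intensities.loc[acc].lt(0)][0]
            raise ValidationError(f"negative intensity for {acc} at column {col}")
        upept = self.records["unique_peptides"]
        if (upept < 0).any():
            raise ValidationError("unique_peptides must be >= 0")
        bad_conf = set(self.records["confidence"]) - set(CONFIDENCE_LEVELS)
        if bad_conf:
            raise ValidationError(f"unknown confidence levels: {sorted(bad_conf)}")

    # -- structure helpers -------------------------------------------------

    @property
    def accessions(self) -> pd.Index:
        return self.records.index

    @property
    def sets(self) -> list[int]:
        return sorted({s for s, _, _ in self.intensities.columns})

    def runs(self, set_id: int) -> list[int]:
        return sorted({r for s, r, _ in self.intensities.columns if s == set_id})

    def channels(self, set_id: int, run_id: int) -> list[str]:
        cols = [c for s, r, c in self.intensities.columns if s == set_id and r == run_id]
        return sorted(cols, key=TMT10_CHANNELS.index)

    @property
    def n_missing(self) -> int:
        return int(self.intensities.isna().to_numpy().sum())

    def copy(self) -> "ReporterIntensityTable":
        return ReporterIntensityTable(self.records.copy(), self.intensities.copy())

    def subset(self, accessions: Iterable[str]) -> "ReporterIntensityTable":
        idx = pd.Index(accessions)
        return ReporterIntensityTable(
            self.records.loc[idx].copy(), self.intensities.loc[idx].copy()
        )

    def equals(self, other: "ReporterIntensityTable") -> bool:
        return self.records.equals(other.records) and self.intensities.equals(
            other.intensities
        )


@dataclass
class AnnotationSets:
    """Gene-set membership (term id -> name + member symbols).

    Symbols are matched case-insensitively across files, so members are
    stored lower-cased and de-duplicated.
    """

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term_id, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"annotation set {term_id} is empty")

    @staticmethod
    def normalize(symbol: str) -> str:
        return symbol.strip().lower()

    @classmethod
    def from_members(cls, sets: Mapping[str, tuple[str, Iterable[str]]]) -> "AnnotationSets":
        return cls(
            {
                term: (name, frozenset(cls.normalize(m) for m in members))
                for term, (name, members) in sets.items()
            }
        )

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()
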