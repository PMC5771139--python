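"""Shared fixtures: small simulated datasets and toy-table builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from adlpquant import (
    ExperimentDesign,
    ReporterIntensityTable,
    SimulationParams,
    simulate_dataset,
)
from adlpquant.datatypes import TMT10_CHANNELS


def make_table(
    values: dict[str, dict[tuple[int, int, str], float]],
    confidence: dict[str, str] | None = None,
    unique_peptides: dict[str, int] | None = None,
) -> ReporterIntensityTable:
    """Build a table from a per-accession {(set, run, channel): value} map.

    Unlisted (set, run, channel) cells of a set mentioned anywhere are
    missing.  Sets are padded to the full 10-channel layout.
    """
    keys = sorted({k for v in values.values() for k in v},
                  key=lambda k: (k[0], k[1], TMT10_CHANNELS.index(k[2])))
    set_runs = sorted({(s, r) for s, r, _ in keys})
    columns = pd.MultiIndex.from_tuples(
        [(s, r, c) for s, r in set_runs for c in TMT10_CHANNELS],
        names=["set", "run", "channel"],
    )
    accessions = pd.Index(values.keys(), name="accession")
    data = np.full((len(accessions), len(columns)), np.nan)
    for i, acc in enumerate(accessions):
        for key, value in values[acc].items():
            data[i, columns.get_loc(key)] = value
    records = pd.DataFrame(
        {
            "gene_symbol": [a.lower() for a in accessions],
            "confidence": [
                (confidence or {}).get(a, "high") for a in accessions
            ],
            "unique_peptides": [
                (unique_peptides or {}).get(a, 3) for a in accessions
            ],
            "description": ["" for _ in accessions],
        },
        index=accessions,
    )
    return ReporterIntensityTable(
        records=records, intensities=pd.DataFrame(data, index=accessions, columns=columns)
    )


def uniform_table(
    design: ExperimentDesign, protein_values: dict[str, float], spike: float = 100.0
) -> ReporterIntensityTable:
    """Table where each protein has one constant intensity in every designed cell."""
    values: dict[str, dict[tuple[int, int, str], float]] = {}
    cells = []
    for (set_id, channel) in list(design.assignments) + [
        (s, c) for s, c in design.pooled_channel.items()
    ]:
        for run in (1, 2):
            cells.append((set_id, run, channel))
    for acc, value in protein_values.items():
        values[acc] = {cell: value for cell in cells}
    values[design.spikein_accession] = {cell: spike for cell in cells}
    return make_table(values)


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    return SimulationParams(n_proteins=300, seed=11)


@pytest.fixture(scope="session")
def dataset(small_params):
    return simulate_dataset(small_params)


@pytest.fixture(scope="session")
def noiseless_params() -> SimulationParams:
    return SimulationParams(
        n_proteins=120,
        seed=5,
        biological_cv=0.0,
        technical_cv=0.0,
        channel_scale_sd=0.0,
        set_scale_sd=0.0,
        batch_protein_sd=0.0,
        missing_rate=0.0,
        frac_low_confidence=0.0,
        frac_zero_unique=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_params):
    return simulate_dataset(noiseless_params)


@pytest.fixture()
def default_design() -> ExperimentDesign:
    return ExperimentDesign.default()
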