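"""Readers and writers for the pipeline's tabular exchange formats.

All formats are plain tab-delimited UTF-8 text:

* **Intensity tables** — one metadata block (``accession``, ``gene_symbol``,
  ``confidence``, ``unique_peptides``, ``description``) followed by one
  intensity column per ``(set, run, channel)`` triple, named
  ``set<k>.run<m>.<channel>`` (TMT 10-plex channel nomenclature).  Empty
  cells are *missing*, never zero.
* **Design files** — one row per channel with its role (sample or pooled)
  and, for samples, the genotype/age/replicate label; the spike-in accession
  is a ``# spikein_accession:`` directive line.
* **GMT** gene-set files and **TSV edge lists** follow their community
  conventions.

Writers emit deterministic column order so re-running a pipeline with the
same seed produces byte-identical artifacts.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import networkx as nx

import pandas as pd

from ._errors import FormatError, ValidationError
from .datatypes import (
    METADATA_COLUMNS,
    TMT10_CHANNELS,
    AnnotationSets,
    ExperimentDesign,
    ReporterIntensityTable,
    SampleLabel,
)

_INTENSITY_COL = re.compile(r"^set(\d+)\.run(\d+)\.(\d{3}[NC]?)$")


# ---------------------------------------------------------------------------
# reporter-ion intensity tables
# ---------------------------------------------------------------------------

def read_intensity_table(path: str | Path) -> ReporterIntensityTable:
    """Parse a reporter-ion intensity table (TSV, or XLSX as an import shim).

    Empty intensity cells become ``NaN`` (missing), which downstream filters
    treat as unquantified — never as zero intensity.  ``.xlsx`` files with
    the same column layout are accepted so spreadsheet exports can be
    re-analyzed directly (requires openpyxl).

    Raises
    ------
    FormatError
        If the header lacks required metadata columns or an intensity column
        name does not match ``set<k>.run<m>.<channel>``.
    ValidationError
        If parsed values violate a table invariant (e.g. negative intensity).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        frame = pd.read_excel(path, dtype={"accession": str},
                              keep_default_na=False, na_values=[""])
    else:
        frame = pd.read_csv(path, sep="\t", dtype={"accession": str},
                            keep_default_na=False, na_values=[""])
    required = ("accession",) + METADATA_COLUMNS
    for col in required:
        if col not in frame.columns:
            raise FormatError(f"{path.name}: missing metadata column {col!r}")
    intensity_cols: list[tuple[int, int, str]] = []
    for col in frame.columns:
        if col in required:
            continue
        m = _INTENSITY_COL.match(col)
        if m is None:
            raise FormatError(
                f"{path.name}: column {col!r} is neither metadata nor a "
                "'set<k>.run<m>.<channel>' intensity column"
            )
        set_id, run_id, channel = int(m.group(1)), int(m.group(2)), m.group(3)
        if channel not in TMT10_CHANNELS:
            raise FormatError(f"{path.name}: {col!r} names unknown TMT channel {channel}")
        intensity_cols.append((set_id, run_id, channel))

    records = frame[list(required)].set_index("accession")
    records["description"] = records["description"].fillna("")
    records["gene_symbol"] = records["gene_symbol"].fillna("")
    try:
        records["unique_peptides"] = records["unique_peptides"].astype(int)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path.name}: non-integer unique_peptides") from exc

    raw = frame.drop(columns=list(required) + ["accession"], errors="ignore")
    raw = frame[[c for c in frame.columns if c not in required]]
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = raw.notna() & values.isna()
    if bad.to_numpy().any():
        col = bad.columns[bad.any(axis=0)][0]
        raise FormatError(f"{path.name}: non-numeric intensity in column {col!r}")
    intensities = values.set_axis(
        pd.MultiIndex.from_tuples(intensity_cols, names=["set", "run", "channel"]),
        axis=1,
    )
    intensities.index = records.index
    neg = intensities.lt(0)
    if neg.to_numpy().any():
        acc = records.index[neg.any(axis=1)][0]
        col = neg.columns[neg.loc[acc]][0]
        raise ValidationError(
            f"{path.name}: negative intensity for {acc} at set{col[0]}.run{col[1]}.{col[2]}"
        )
    return ReporterIntensityTable(records=records, intensities=intensities)


def write_intensity_table(table: ReporterIntensityTable, path: str | Path) -> None:
    """Write a table in the format :func:`read_intensity_table` parses.

    Missing intensities are written as empty cells; round-tripping preserves
    the count and location of missing values exactly.
    """
    path = Path(path)
    cols = sorted(
        table.intensities.columns,
        key=lambda c: (c[0], c[1], TMT10_CHANNELS.index(c[2])),
    )
    out = table.records.rename_axis("accession").reset_index()
    out = out[["accession", *METADATA_COLUMNS]].copy()
    for set_id, run_id, channel in cols:
        out[f"set{set_id}.run{run_id}.{channel}"] = table.intensities[
            (set_id, run_id, channel)
        ].to_numpy()
    out.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# experiment design
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> ExperimentDesign:
    """Parse a channel-to-sample design file.

    Expected layout: optional ``# spikein_accession: <acc>`` directive, a
    header ``set\\tchannel\\trole\\tgenotype\\tage_months\\treplicate``, then one
    row per channel.  Role is ``sample`` or ``pooled``.
    """
    path = Path(path)
    spikein = "OVALBUMIN_SPIKE"
    rows: list[list[str]] = []
    header: list[str] | None = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*spikein_accession\s*[:=]\s*(\S+)", line)
            if m:
                spikein = m.group(1)
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            expected = ["set", "channel", "role", "genotype", "age_months", "replicate"]
            if header != expected:
                raise FormatError(
                    f"{path.name}:{lineno}: design header must be {expected}, got {header}"
                )
            continue
        rows.append(fields + [""] * (6 - len(fields)))
    if header is None:
        raise FormatError(f"{path.name}: empty design file")

    assignments: dict[tuple[int, str], SampleLabel] = {}
    pooled: dict[int, str] = {}
    for fields in rows:
        set_id = int(fields[0])
        channel = fields[1].strip()
        role = fields[2].strip().lower()
        if role == "pooled":
            if set_id in pooled:
                raise ValidationError(
                    f"{path.name}: set {set_id} declares two pooled channels "
                    f"({pooled[set_id]} and {channel})"
                )
            pooled[set_id] = channel
        elif role == "sample":
            label = SampleLabel(fields[3].strip(), int(fields[4]), int(fields[5]))
            if (set_id, channel) in assignments:
                raise ValidationError(
                    f"{path.name}: channel {channel} of set {set_id} assigned twice"
                )
            assignments[(set_id, channel)] = label
        else:
            raise FormatError(f"{path.name}: unknown channel role {role!r}")
    # duplicate-label and per-set pooled-channel invariants are enforced here
    return ExperimentDesign(
        assignments=assignments, pooled_channel=pooled, spikein_accession=spikein
    )


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# spikein_accession: {design.spikein_accession}",
             "set\tchannel\trole\tgenotype\tage_months\treplicate"]
    entries: list[tuple[int, str, str, str, str, str]] = []
    for (set_id, channel), label in design.assignments.items():
        entries.append((set_id, channel, "sample", label.genotype,
                        str(label.age_months), str(label.replicate)))
    for set_id, channel in design.pooled_channel.items():
        entries.append((set_id, channel, "pooled", "", "", ""))
    entries.sort(key=lambda e: (e[0], TMT10_CHANNELS.index(e[1])))
    lines += ["\t".join(map(str, e)) for e in entries]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# gene sets (GMT) and PPI edge lists
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> AnnotationSets:
    """Parse a GMT gene-set file (term id, term name, members...).

    Members are de-duplicated and matched case-insensitively downstream.
    """
    path = Path(path)
    sets: dict[str, tuple[str, Iterable[str]]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path.name}:{lineno}: GMT line needs >=3 tab-separated fields"
            )
        term_id, term_name, *members = fields
        members = [m for m in members if m.strip()]
        if not members:
            raise FormatError(f"{path.name}:{lineno}: gene set {term_id} has no members")
        sets[term_id] = (term_name, members)
    return AnnotationSets.from_members(sets)


def write_gmt(sets: AnnotationSets, path: str | Path) -> None:
    lines = [
        "\t".join([term, name, *sorted(members)])
        for term, (name, members) in sorted(sets.items())
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_ppi_edges(path: str | Path, min_score: float = 0.0) -> nx.Graph:
    """Parse a symbol_a/symbol_b/score TSV into an undirected PPI graph.

    Edges below ``min_score`` and self-loops are dropped; duplicate edges in
    either orientation collapse to one undirected edge (last score wins).
    Symbols are matched case-insensitively (stored lower-case).
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValidationError(f"min_score must lie in [0, 1], got {min_score}")
    path = Path(path)
    graph = nx.Graph()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path.name}:{lineno}: edge line needs 3 fields")
        a = AnnotationSets.normalize(fields[0])
        b = AnnotationSets.normalize(fields[1])
        try:
            score = float(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path.name}:{lineno}: non-numeric score") from exc
        if not 0.0 <= score <= 1.0:
            raise ValidationError(
                f"{path.name}:{lineno}: confidence score {score} outside [0, 1]"
            )
        if a == b:
            continue  # self-loops carry no bridge information
        if score >= min_score:
            graph.add_edge(a, b, score=score)
    return graph


def write_ppi_edges(graph: nx.Graph, path: str | Path) -> None:
    lines = [
        f"{a}\t{b}\t{data.get('score', 1.0):g}"
        for a, b, data in sorted(graph.edges(data=True))
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# abundance matrices (protein x sample)
# ---------------------------------------------------------------------------

def write_abundance_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a protein x sample matrix with ``genotype.age.rN`` column labels."""
    out = matrix.copy()
    out.columns = [str(SampleLabel(*c)) for c in matrix.columns]
    out.index.name = "accession"
    out.to_csv(path, sep="\t")


def read_abundance_matrix(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col="accession")
    labels = [SampleLabel.parse(c) for c in frame.columns]
    frame.columns = pd.MultiIndex.from_tuples(
        [(l.genotype, l.age_months, l.replicate) for l in labels],
        names=["genotype", "age_months", "replicate"],
    )
    return frame
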