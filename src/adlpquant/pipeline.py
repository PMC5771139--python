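"""End-to-end orchestration: simulate -> normalize -> qc -> dep -> enrich -> network.

One structured config drives every stage; every artifact is written under a
single output directory and listed, with its SHA-256 checksum, in a run
manifest that also carries the seed and a hash of the resolved config.
Re-running with an identical config reproduces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from ._errors import ValidationError
from .datatypes import SampleLabel
from .dep import anova_dep, exclusive_deps, hierarchical_cluster, ttest_dep, znormalize
from .enrich import fisher_enrichment
from .io import (
    read_design,
    read_gmt,
    read_intensity_table,
    read_ppi_edges,
    write_abundance_matrix,
    write_design,
    write_intensity_table,
    write_ppi_edges,
)
from .network import build_subnetwork, find_bridges
from .normalize import (
    compute_fold_change,
    compute_normalized_abundance,
    filter_quantifiable,
    merge_technical_duplicates,
    spikein_normalize,
)
from .qc import compute_qc_report
from .simulate import (
    SimulationParams,
    simulate_annotation_sets,
    simulate_dataset,
    simulate_ppi_graph,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "qc", "dep", "enrich", "network")
_STAGE_DEPS = {
    "normalize": ("simulate",),
    "qc": ("normalize",),
    "dep": ("normalize",),
    "enrich": ("dep",),
    "network": ("dep",),
}
TRANSGENIC = ("APP_PS1", "Tau", "APT")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    simulate: dict[str, Any] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)  # table/design when not simulating
    alpha: float = 0.05
    fc_cut: float = 1.25
    fdr: float = 0.05
    k_all_models: int = 3
    k_target: int = 5
    target_genotype: str = "APT"
    p_cutoff: float = 0.01
    gmt: str | None = None
    ppi_edges: str | None = None
    min_score: float = 0.4
    max_len: int = 3
    anchors: tuple[str, str] = ("App", "Mapt")

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        for stage in self.stages:
            for needed in _STAGE_DEPS.get(stage, ()):
                if needed in ("simulate",) and self.inputs.get("table"):
                    continue  # externally supplied table satisfies the dependency
                if needed not in self.stages:
                    raise ValidationError(
                        f"stage {stage!r} requires stage {needed!r} to be enabled"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "anchors" in raw:
            raw["anchors"] = tuple(raw["anchors"])
        return cls(**raw)

    def to_canonical(self) -> str:
        payload = dataclasses.asdict(self)
        payload["outdir"] = str(payload["outdir"])
        payload["stages"] = list(payload["stages"])
        payload["anchors"] = list(payload["anchors"])
        return json.dumps(payload, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical().encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, config: PipelineConfig):
        self.payload: dict[str, Any] = {
            "seed": config.seed,
            "config_hash": config.config_hash,
            "stages": list(config.stages),
            "artifacts": {},
        }
        self.outdir = config.outdir

    def add(self, name: str, path: Path) -> None:
        self.payload["artifacts"][name] = {
            "path": str(path.relative_to(self.outdir)),
            "sha256": _sha256(path),
        }

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.payload, indent=2, sort_keys=True) + "\n")
        return path


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the enabled stages in dependency order; return the manifest."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    state: dict[str, Any] = {}

    for stage in STAGES:
        if stage not in config.stages:
            continue
        logger.info("stage %s: starting", stage)
        try:
            _STAGE_RUNNERS[stage](config, state, manifest)
        except Exception as exc:
            raise ValidationError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s: done", stage)

    path = manifest.write()
    logger.info("manifest written to %s", path)
    return manifest.payload


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, state: dict, manifest: _Manifest) -> None:
    params = SimulationParams(**{**config.simulate, "seed": config.seed})
    table, design, truth = simulate_dataset(params)
    state.update(raw_table=table, design=design, truth=truth, params=params)
    write_intensity_table(table, config.outdir / "table.tsv")
    write_design(design, config.outdir / "design.tsv")
    sidecar = pd.DataFrame(
        {
            "gene_symbol": truth.gene_symbols,
            "archetype": truth.archetype,
            "base_abundance": truth.base_abundance,
        }
    )
    sidecar.to_csv(config.outdir / "ground_truth.tsv", sep="\t")
    manifest.add("table", config.outdir / "table.tsv")
    manifest.add("design", config.outdir / "design.tsv")
    manifest.add("ground_truth", config.outdir / "ground_truth.tsv")


def _stage_normalize(config: PipelineConfig, state: dict, manifest: _Manifest) -> None:
    if "raw_table" not in state:
        state["raw_table"] = read_intensity_table(config.inputs["table"])
        state["design"] = read_design(config.inputs["design"])
    table, design = state["raw_table"], state["design"]
    normalized = spikein_normalize(table, design)
    merged = merge_technical_duplicates(normalized)
    filtered, report = filter_quantifiable(merged, design)
    matrix = compute_normalized_abundance(filtered, design)
    fold = compute_fold_change(matrix, design)
    state.update(filtered=filtered, matrix=matrix, fold_changes=fold,
                 filter_report=report)
    write_abundance_matrix(matrix, config.outdir / "normalized_abundance.tsv")
    fold_out = fold.copy()
    fold_out.columns = [f"{g}.{a}" for g, a in fold.columns]
    fold_out.to_csv(config.outdir / "fold_changes.tsv", sep="\t")
    pd.DataFrame([dataclasses.asdict(report)]).to_csv(
        config.outdir / "filter_report.tsv", sep="\t", index=False
    )
    manifest.add("normalized_abundance", config.outdir / "normalized_abundance.tsv")
    manifest.add("fold_changes", config.outdir / "fold_changes.tsv")
    manifest.add("filter_report", config.outdir / "filter_report.tsv")


def _stage_qc(config: PipelineConfig, state: dict, manifest: _Manifest) -> None:
    report = compute_qc_report(state["raw_table"], state["matrix"], state["design"])
    state["qc_report"] = report
    report.to_frame().to_csv(config.outdir / "qc_report.tsv", sep="\t", index=False)
    manifest.add("qc_report", config.outdir / "qc_report.tsv")


def _stage_dep(config: PipelineConfig, state: dict, manifest: _Manifest) -> None:
    matrix = state["matrix"]
    ages = sorted({a for _, a, _ in matrix.columns})
    genotypes = [g for g in TRANSGENIC if g in {c[0] for c in matrix.columns}]
    ttests: dict[str, dict[int, pd.DataFrame]] = {}
    for genotype in genotypes:
        ttests[genotype] = {}
        for age in ages:
            result = ttest_dep(matrix, genotype, age,
                               alpha=config.alpha, fc_cut=config.fc_cut)
            ttests[genotype][age] = result
            path = config.outdir / f"ttest_{genotype}_{age}mo.tsv"
            result.to_csv(path, sep="\t")
            manifest.add(f"ttest_{genotype}_{age}mo", path)

    all_groups = [(g, a) for g in ("WT", *genotypes) for a in ages]
    anova_all = anova_dep(matrix, all_groups, fdr=config.fdr)
    anova_all.to_csv(config.outdir / "anova_all_models.tsv", sep="\t")
    manifest.add("anova_all_models", config.outdir / "anova_all_models.tsv")

    target = config.target_genotype
    target_groups = [(g, a) for g in ("WT", target) for a in ages]
    anova_target = anova_dep(matrix, target_groups, fdr=config.fdr)
    anova_target.to_csv(config.outdir / f"anova_{target}.tsv", sep="\t")
    manifest.add(f"anova_{target}", config.outdir / f"anova_{target}.tsv")

    def cluster(dep_frame: pd.DataFrame, k: int, name: str):
        hits = dep_frame.index[dep_frame["significant"]]
        if len(hits) < k:
            logger.warning("%s: %d significant proteins < k=%d, skipping clustering",
                           name, len(hits), k)
            return None
        assignment = hierarchical_cluster(znormalize(matrix.loc[hits]), k)
        out = assignment.labels.to_frame()
        path = config.outdir / f"clusters_{name}.tsv"
        out.to_csv(path, sep="\t")
        manifest.add(f"clusters_{name}", path)
        return assignment

    state["clusters_all"] = cluster(anova_all, config.k_all_models, "all_models")
    state["clusters_target"] = cluster(anova_target, config.k_target, target)

    early_late = [a for a in (min(ages), max(ages))]
    exclusive = exclusive_deps(
        {g: ttests[g] for g in genotypes}, state["fold_changes"],
        target=target, ages=early_late, fc_cut=config.fc_cut,
    )
    state.update(ttests=ttests, anova_all=anova_all, anova_target=anova_target,
                 exclusive=sorted(exclusive))
    pd.Series(sorted(exclusive), name="accession").to_csv(
        config.outdir / "exclusive_deps.tsv", sep="\t", index=False
    )
    manifest.add("exclusive_deps", config.outdir / "exclusive_deps.tsv")


def _symbols_of(state: dict, accessions) -> list[str]:
    records = state["filtered"].records
    return [s for s in records.loc[accessions, "gene_symbol"] if s]


def _stage_enrich(config: PipelineConfig, state: dict, manifest: _Manifest) -> None:
    background = _symbols_of(state, state["matrix"].index)
    if config.gmt:
        sets = read_gmt(config.gmt)
    else:
        planted = {}
        if "truth" in state:
            truth = state["truth"]
            for archetype in ("up_gradual", "down_gradual"):
                members = truth.gene_symbols[truth.archetype == archetype]
                if len(members):
                    planted[f"PLANTED:{archetype}"] = list(members)
        sets = simulate_annotation_sets(background, seed=config.seed, planted=planted)
    assignment = state.get("clusters_target")
    frames = []
    if assignment is not None:
        for cluster_id in sorted(assignment.sizes().index):
            fg = _symbols_of(state, assignment.members(cluster_id))
            result = fisher_enrichment(fg, background, sets, p_cutoff=config.p_cutoff)
            result.insert(0, "cluster", cluster_id)
            frames.append(result)
    enrichment = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    enrichment.to_csv(config.outdir / "enrichment.tsv", sep="\t", index=False)
    state["enrichment"] = enrichment
    manifest.add("enrichment", config.outdir / "enrichment.tsv")


def _stage_network(config: PipelineConfig, state: dict, manifest: _Manifest) -> None:
    exclusive_symbols = _symbols_of(state, pd.Index(state["exclusive"]))
    if config.ppi_edges:
        graph = read_ppi_edges(config.ppi_edges, min_score=config.min_score)
    else:
        graph = simulate_ppi_graph(
            sorted(set(_symbols_of(state, state["matrix"].index))),
            anchors=config.anchors,
            bridge_symbols=sorted(exclusive_symbols)[:3],
            seed=config.seed,
        )
    fold = state["fold_changes"]
    records = state["filtered"].records
    symbol_fc: dict[str, dict[int, float]] = {}
    target = config.target_genotype
    ages = sorted({a for _, a in fold.columns if _ == target})
    for acc in state["exclusive"]:
        symbol = records.loc[acc, "gene_symbol"]
        if symbol:
            symbol_fc[symbol] = {a: float(fold.loc[acc, (target, a)]) for a in ages}
    report = find_bridges(graph, *config.anchors, max_len=config.max_len,
                          fold_changes=symbol_fc)
    rows = [
        {"node": node, "shortest_path_len": length,
         **{f"fc_{a}mo": report.fold_changes.get(node, {}).get(a, float("nan"))
            for a in ages}}
        for node, length in sorted(report.bridges.items())
    ]
    pd.DataFrame(rows).to_csv(config.outdir / "bridge_report.tsv", sep="\t", index=False)
    sub = build_subnetwork(graph, exclusive_symbols, config.anchors,
                           max_len=config.max_len)
    write_ppi_edges(sub, config.outdir / "subnetwork_edges.tsv")
    state["bridge_report"] = report
    manifest.add("bridge_report", config.outdir / "bridge_report.tsv")
    manifest.add("subnetwork_edges", config.outdir / "subnetwork_edges.tsv")


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "qc": _stage_qc,
    "dep": _stage_dep,
    "enrich": _stage_enrich,
    "network": _stage_network,
}
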