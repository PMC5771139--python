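"""PPI subnetwork construction and anchor-to-anchor bridge extraction.

The bridge analysis asks which proteins lie on short interaction paths
between two anchor proteins (App and Mapt in the study: the amyloid and the
tau axis), i.e. which candidates could couple the two pathologies.  A
*bridge node* is any non-anchor node on at least one simple anchor-to-anchor
path of at most ``max_len`` edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from ._errors import ValidationError
from .datatypes import AnnotationSets


@dataclass
class BridgeReport:
    """Bridge nodes between an anchor pair, with shortest admissible path length."""

    anchors: tuple[str, str]
    max_len: int
    #: node -> length (in edges) of its shortest admissible anchor-to-anchor path
    bridges: dict[str, int] = field(default_factory=dict)
    #: optional per-node fold changes at selected ages, e.g. {node: {4: fc, 10: fc}}
    fold_changes: dict[str, dict[int, float]] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.bridges)


def _require_anchor(graph: nx.Graph, anchor: str) -> str:
    normed = AnnotationSets.normalize(anchor)
    if normed not in graph:
        raise ValidationError(f"anchor {anchor!r} absent from the PPI graph")
    return normed


def find_bridges(
    graph: nx.Graph,
    anchor_a: str,
    anchor_b: str,
    max_len: int = 3,
    fold_changes: Mapping[str, Mapping[int, float]] | None = None,
) -> BridgeReport:
    """All non-anchor nodes on a simple anchor-to-anchor path of <= max_len edges.

    Disconnected anchors (within ``max_len``) yield an empty bridge set, not
    an error.  When ``fold_changes`` is supplied, each bridge node is
    annotated with its values.  The result is symmetric in the anchors and
    grows monotonically with ``max_len``.
    """
    a = _require_anchor(graph, anchor_a)
    b = _require_anchor(graph, anchor_b)
    if max_len < 1:
        raise ValidationError("max_len must be >= 1")
    bridges: dict[str, int] = {}
    for path in nx.all_simple_paths(graph, a, b, cutoff=max_len):
        length = len(path) - 1
        for node in path[1:-1]:
            if node not in bridges or length < bridges[node]:
                bridges[node] = length
    annotated = {}
    if fold_changes:
        lookup = {AnnotationSets.normalize(k): dict(v) for k, v in fold_changes.items()}
        annotated = {
            node: lookup[AnnotationSets.normalize(node)]
            for node in bridges
            if AnnotationSets.normalize(node) in lookup
        }
    return BridgeReport(
        anchors=(a, b), max_len=max_len, bridges=bridges, fold_changes=annotated
    )


def build_subnetwork(
    graph: nx.Graph,
    nodes: Iterable[str],
    anchors: tuple[str, str],
    max_len: int = 3,
) -> nx.Graph:
    """Induced subgraph on the input nodes, the anchors, and their bridge nodes.

    Input nodes with no edge inside the subnetwork are retained and flagged
    with the node attribute ``isolated=True`` so downstream rendering can
    show them apart.
    """
    a = _require_anchor(graph, anchors[0])
    b = _require_anchor(graph, anchors[1])
    wanted = {AnnotationSets.normalize(n) for n in nodes}
    bridge_nodes = set(find_bridges(graph, a, b, max_len=max_len).bridges)
    keep = (wanted | {a, b} | bridge_nodes) & set(graph.nodes)
    sub = graph.subgraph(keep).copy()
    missing = wanted - set(graph.nodes)
    sub.add_nodes_from(missing)  # requested but unknown to the PPI source
    for node in sub.nodes:
        sub.nodes[node]["isolated"] = sub.degree(node) == 0
    return sub
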