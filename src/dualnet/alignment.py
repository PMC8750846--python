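"""Weighted alignment-graph construction for dual networks.

The two layers of a dual network are merged into a single weighted graph
whose nodes are the correspondence pairs (v, w) — one physical member, one
conceptual member — and whose edges are typed by how the two layers agree:

* **Match** — the physical members are adjacent in the physical network and
  the conceptual members are adjacent in the conceptual network.  The edge
  inherits the conceptual weight.
* **Gap** — exactly one layer has the direct edge, and in the other layer
  the counterpart members are within shortest-path distance δ (unweighted
  hop count).  δ = 1 demands adjacency, so an absent counterpart edge
  (distance ≥ 2) admits no Gap at δ = 1.

Pairs with neither relationship get no edge; a correspondence pair with no
qualifying neighbour at all stays in the graph as an isolated node.

Because every edge built with δ = 1 joins alignment nodes whose physical
members are adjacent, any connected subgraph of a δ = 1 alignment graph
projects onto a connected subgraph of the physical network — the property
the downstream community search relies on.
"""

from __future__ import annotations

from typing import Iterable, Literal

import networkx as nx

from .model import DualNetwork, DualNetworkError

__all__ = [
    "MATCH",
    "GAP",
    "build_alignment_graph",
    "project_to_physical",
    "project_to_conceptual",
]

MATCH = "MATCH"
GAP = "GAP"

GapMode = Literal["symmetric", "physical_edge_only", "conceptual_edge_only"]

AlignmentNode = tuple[str, str]


class _BoundedDistance:
    """Cached unweighted shortest-path queries with a hop cutoff."""

    def __init__(self, graph: nx.Graph, cutoff: int):
        self.graph = graph
        self.cutoff = cutoff
        self._cache: dict[str, dict[str, int]] = {}

    def within(self, a: str, b: str) -> bool:
        if a not in self.graph or b not in self.graph:
            return False
        if a not in self._cache:
            self._cache[a] = nx.single_source_shortest_path_length(
                self.graph, a, cutoff=self.cutoff
            )
        return b in self._cache[a]


def build_alignment_graph(
    dn: DualNetwork,
    delta: int = 1,
    gap_weight: float | None = None,
    gap_mode: GapMode = "symmetric",
) -> nx.Graph:
    """Merge a dual network into its weighted alignment graph.

    Parameters
    ----------
    dn
        Validated dual network.
    delta
        Maximum hop distance allowed on the counterpart layer for a Gap
        edge; must be ≥ 1.
    gap_weight
        Weight for Gap edges whose conceptual counterpart edge does not
        exist (the physical-edge direction).  Defaults to the minimum
        conceptual edge weight of the input — a conservative "weak tie" that
        keeps every weight positive without letting gaps dominate.  Gap
        edges in the conceptual-edge direction keep their conceptual weight.
    gap_mode
        Which direction(s) may create Gap edges.  ``symmetric`` (default)
        accepts a direct edge in either layer with a bounded path in the
        other; the one-sided modes restrict to the named layer's direct
        edges.

    Returns
    -------
    networkx.Graph
        Nodes are (physical, conceptual) pairs; edges carry ``weight`` and
        ``kind`` (``MATCH``/``GAP``); graph attributes record ``delta``,
        ``gap_weight`` and ``gap_mode``.
    """
    if delta < 1:
        raise DualNetworkError(f"delta must be a positive integer, got {delta}")
    if gap_mode not in ("symmetric", "physical_edge_only", "conceptual_edge_only"):
        raise DualNetworkError(f"unknown gap_mode {gap_mode!r}")
    dn.validate()

    phys, conc = dn.physical, dn.conceptual
    if gap_weight is None:
        weights = [d["weight"] for _, _, d in conc.edges(data=True)]
        gap_weight = min(weights) if weights else 1.0
    if not gap_weight > 0:
        raise DualNetworkError(f"gap_weight must be positive, got {gap_weight}")

    graph = nx.Graph(delta=delta, gap_weight=gap_weight, gap_mode=gap_mode)
    graph.add_nodes_from(dn.mapping)

    # Index alignment nodes by each member so candidate pairs can be
    # enumerated from the two edge lists instead of all O(k^2) node pairs.
    by_phys: dict[str, list[AlignmentNode]] = {}
    by_conc: dict[str, list[AlignmentNode]] = {}
    for pair in dn.mapping:
        by_phys.setdefault(pair[0], []).append(pair)
        by_conc.setdefault(pair[1], []).append(pair)

    candidates: set[tuple[AlignmentNode, AlignmentNode]] = set()

    def add_candidates(index: dict[str, list[AlignmentNode]], u: str, v: str) -> None:
        for a in index.get(u, ()):
            for b in index.get(v, ()):
                if a != b:
                    candidates.add((a, b) if a <= b else (b, a))

    for u, v in phys.edges():
        add_candidates(by_phys, u, v)
    for u, v in conc.edges():
        add_candidates(by_conc, u, v)

    conc_dist = _BoundedDistance(conc, delta)
    phys_dist = _BoundedDistance(phys, delta)

    for a, b in candidates:
        va, wa = a
        vb, wb = b
        phys_edge = phys.has_edge(va, vb)
        conc_edge = conc.has_edge(wa, wb)
        if phys_edge and conc_edge:
            graph.add_edge(a, b, weight=float(conc[wa][wb]["weight"]), kind=MATCH)
        elif phys_edge and gap_mode in ("symmetric", "physical_edge_only"):
            if conc_dist.within(wa, wb):
                graph.add_edge(a, b, weight=float(gap_weight), kind=GAP)
        elif conc_edge and gap_mode in ("symmetric", "conceptual_edge_only"):
            if phys_dist.within(va, vb):
                graph.add_edge(a, b, weight=float(conc[wa][wb]["weight"]), kind=GAP)
    return graph


def project_to_physical(subgraph_nodes: Iterable[AlignmentNode]) -> set[str]:
    """Distinct physical members of a set of alignment nodes."""
    return {v for v, _ in subgraph_nodes}


def project_to_conceptual(subgraph_nodes: Iterable[AlignmentNode]) -> set[str]:
    """Distinct conceptual members of a set of alignment nodes."""
    return {w for _, w in subgraph_nodes}
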