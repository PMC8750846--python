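"""Greedy densest-subgraph extraction (weighted Charikar peeling).

Density of a node set S is w(S)/|S|, the total weight of edges internal to
S divided by the number of nodes — the natural weighted extension of the
classic |E|/|V| objective.  Peeling repeatedly deletes the node of minimum
weighted degree and returns the densest prefix; this is a ½-approximation
of the optimum, and on unit weights it coincides with the classic
unweighted algorithm.  Ties in the minimum weighted degree break on the
lexicographically smallest node identifier so the procedure is
deterministic.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, replace

import networkx as nx

from .alignment import build_alignment_graph
from .communities import Community, refine_connectivity
from .model import DualNetwork, DualNetworkError

__all__ = ["DensityScore", "charikar_peel", "subgraph_density", "find_dcs"]


@dataclass(frozen=True)
class DensityScore:
    """A node set together with its weighted density w(S)/|S|."""

    nodes: frozenset
    density: float


def subgraph_density(graph: nx.Graph, nodes) -> float:
    """Weighted density of the subgraph induced by ``nodes`` (0 if empty)."""
    nodes = set(nodes)
    if not nodes:
        return 0.0
    weight = sum(
        d.get("weight", 1.0)
        for u, v, d in graph.edges(nodes, data=True)
        if u in nodes and v in nodes
    )
    return weight / len(nodes)


def charikar_peel(graph: nx.Graph) -> DensityScore:
    """Peel minimum-weighted-degree nodes; return the densest prefix.

    Guarantees density ≥ ½ of the optimum over all subsets.
    """
    if graph.number_of_nodes() == 0:
        raise DualNetworkError("cannot peel an empty graph")
    degree = {
        n: float(graph.degree(n, weight="weight")) for n in graph.nodes
    }
    total = sum(degree.values()) / 2.0
    remaining = set(graph.nodes)
    # lazy-deletion heap keyed (weighted degree, str(node)) for the tie-break
    heap = [(d, str(n), n) for n, d in degree.items()]
    heapq.heapify(heap)

    best_nodes = frozenset(remaining)
    best_density = total / len(remaining)
    removal_order = []

    while len(remaining) > 1:
        while True:
            d, _, node = heapq.heappop(heap)
            if node in remaining and degree[node] == d:
                break
        remaining.discard(node)
        removal_order.append(node)
        total -= degree[node]
        for nbr, data in graph[node].items():
            if nbr in remaining:
                degree[nbr] -= data.get("weight", 1.0)
                heapq.heappush(heap, (degree[nbr], str(nbr), nbr))
        density = total / len(remaining)
        if density > best_density:
            best_density = density
            best_nodes = frozenset(remaining)
    return DensityScore(nodes=best_nodes, density=best_density)


def find_dcs(
    dn: DualNetwork,
    delta: int = 1,
    min_size: int = 2,
    gap_weight: float | None = None,
    gap_mode: str = "symmetric",
) -> Community | None:
    """Densest connected subgraph of a dual network.

    Peels the alignment graph for the densest node set, then enforces
    physical connectivity with the same component-selection refinement the
    modular pipeline uses.  The reported density is measured on the
    conceptual projection (internal conceptual edge weight per conceptual
    node).  Returns ``None`` with a warning when the refined result falls
    below ``min_size``.
    """
    graph = build_alignment_graph(dn, delta=delta, gap_weight=gap_weight, gap_mode=gap_mode)
    if graph.number_of_nodes() == 0:
        raise DualNetworkError("alignment graph has no nodes")
    peeled = charikar_peel(graph)
    community = Community.from_alignment_nodes(peeled.nodes)
    community = refine_connectivity(community, dn.physical, dn.conceptual)
    density = subgraph_density(dn.conceptual, community.conceptual_nodes)
    community = replace(community, density=density)
    if len(community) < min_size:
        warnings.warn(
            f"densest connected subgraph has {len(community)} node(s), "
            f"below min_size={min_size}",
            stacklevel=2,
        )
        return None
    return community
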