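"""Modular-community detection on the alignment graph.

The pipeline finds node sets that are simultaneously modular in the
conceptual layer and connected in the physical layer:

1. build the weighted alignment graph;
2. partition it with the Louvain heuristic (weighted Newman–Girvan
   modularity, optional resolution γ);
3. refine each community so that its physical projection induces a
   connected subgraph, by keeping the best connected component of the
   induced physical subgraph;
4. drop communities below ``min_size`` and rank the rest by their
   modularity contribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import networkx as nx

from .alignment import build_alignment_graph, project_to_conceptual, project_to_physical
from .model import DualNetwork, DualNetworkError

__all__ = [
    "Community",
    "Partition",
    "louvain_partition",
    "modularity",
    "community_contribution",
    "refine_connectivity",
    "detect_modular_communities",
]


@dataclass(frozen=True)
class Community:
    """A detected community: alignment nodes plus their layer projections."""

    alignment_nodes: frozenset[tuple[str, str]]
    physical_nodes: frozenset[str]
    conceptual_nodes: frozenset[str]
    modularity_contribution: float = 0.0
    connected_in_physical: bool = False
    density: float | None = None

    @classmethod
    def from_alignment_nodes(
        cls,
        nodes,
        modularity_contribution: float = 0.0,
        connected_in_physical: bool = False,
        density: float | None = None,
    ) -> "Community":
        nodes = frozenset(nodes)
        return cls(
            alignment_nodes=nodes,
            physical_nodes=frozenset(project_to_physical(nodes)),
            conceptual_nodes=frozenset(project_to_conceptual(nodes)),
            modularity_contribution=modularity_contribution,
            connected_in_physical=connected_in_physical,
            density=density,
        )

    def __len__(self) -> int:
        return len(self.alignment_nodes)


@dataclass(frozen=True)
class Partition:
    """A disjoint cover of every graph node, with its overall modularity Q."""

    communities: tuple[frozenset, ...]
    modularity: float

    def labels(self) -> dict:
        return {node: i for i, block in enumerate(self.communities) for node in block}


def modularity(graph: nx.Graph, communities, resolution: float = 1.0) -> float:
    """Weighted Newman–Girvan modularity Q of a partition.

    Q = (1/2m) Σ_ij [A_ij − γ k_i k_j / 2m] δ(c_i, c_j), with A the weighted
    adjacency, k the weighted degrees and m the total edge weight.  A graph
    with zero total edge weight has Q defined as 0.
    """
    if graph.size(weight="weight") == 0:
        return 0.0
    return nx.community.modularity(graph, communities, weight="weight", resolution=resolution)


def community_contribution(graph: nx.Graph, nodes, resolution: float = 1.0) -> float:
    """One community's additive term of Q: Σ_in/2m − γ (Σ_tot/2m)²."""
    m2 = 2.0 * graph.size(weight="weight")
    if m2 == 0:
        return 0.0
    nodes = set(nodes)
    sigma_in = 2.0 * sum(
        d.get("weight", 1.0)
        for u, v, d in graph.edges(nodes, data=True)
        if u in nodes and v in nodes
    )
    sigma_tot = sum(graph.degree(n, weight="weight") for n in nodes)
    return sigma_in / m2 - resolution * (sigma_tot / m2) ** 2


def louvain_partition(graph: nx.Graph, resolution: float = 1.0, seed: int = 42) -> Partition:
    """Louvain greedy modularity optimisation; deterministic given ``seed``.

    An edgeless graph yields the all-singletons partition with Q = 0.
    """
    if graph.number_of_nodes() == 0:
        raise DualNetworkError("cannot partition an empty graph")
    if graph.number_of_edges() == 0:
        blocks = tuple(frozenset([n]) for n in sorted(graph.nodes, key=str))
        return Partition(communities=blocks, modularity=0.0)
    blocks = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed
    )
    blocks = tuple(frozenset(b) for b in sorted(blocks, key=lambda b: sorted(map(str, b))))
    return Partition(
        communities=blocks,
        modularity=modularity(graph, blocks, resolution=resolution),
    )


def _conceptual_weight(conceptual: nx.Graph | None, nodes: set[str]) -> float:
    if conceptual is None:
        return 0.0
    return sum(
        d["weight"]
        for u, v, d in conceptual.edges(nodes, data=True)
        if u in nodes and v in nodes
    )


def refine_connectivity(
    community: Community,
    physical: nx.Graph,
    conceptual: nx.Graph | None = None,
) -> Community:
    """Shrink a community until its physical projection is connected.

    Nodes are removed by restricting the community to one connected
    component of the physical subgraph induced by its projection.  The kept
    component maximises, in order: (1) node count, (2) total internal
    conceptual edge weight of the corresponding conceptual projection,
    (3) smallest node identifier (lexicographic).  The result is always a
    subset of the input and the operation is idempotent.
    """
    if not community.alignment_nodes:
        raise DualNetworkError("cannot refine an empty community")
    induced = physical.subgraph(community.physical_nodes)
    components = [set(c) for c in nx.connected_components(induced)]
    # Mapped-but-absent physical nodes have no place in the induced graph;
    # treat each as its own (isolated) component.
    missing = community.physical_nodes - set(induced.nodes)
    components.extend({n} for n in missing)

    def score(comp: set[str]) -> tuple:
        members = {p for p in community.alignment_nodes if p[0] in comp}
        weight = _conceptual_weight(conceptual, project_to_conceptual(members))
        return (-len(comp), -weight, min(map(str, comp)))

    best = min(components, key=score)
    kept = frozenset(p for p in community.alignment_nodes if p[0] in best)
    return replace(
        Community.from_alignment_nodes(kept),
        modularity_contribution=community.modularity_contribution,
        connected_in_physical=True,
        density=community.density,
    )


def detect_modular_communities(
    dn: DualNetwork,
    delta: int = 1,
    resolution: float = 1.0,
    seed: int = 42,
    min_size: int = 3,
    gap_weight: float | None = None,
    gap_mode: str = "symmetric",
) -> list[Community]:
    """Full modular-community pipeline on a dual network.

    Returns communities whose physical projections are connected, each at
    least ``min_size`` alignment nodes, sorted by modularity contribution
    (descending).  Isolated alignment nodes stay in the graph but fall to
    the ``min_size`` filter.
    """
    graph = build_alignment_graph(dn, delta=delta, gap_weight=gap_weight, gap_mode=gap_mode)
    partition = louvain_partition(graph, resolution=resolution, seed=seed)
    results: list[Community] = []
    for block in partition.communities:
        contribution = community_contribution(graph, block, resolution=resolution)
        community = Community.from_alignment_nodes(block, modularity_contribution=contribution)
        community = refine_connectivity(community, dn.physical, dn.conceptual)
        if len(community) >= min_size:
            results.append(community)
    results.sort(key=lambda c: (-c.modularity_contribution, sorted(c.alignment_nodes)))
    return results
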