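import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from dualnet import SyntheticSpec, assemble_dual_network, generate_dual_network


@pytest.fixture
def seven_pair_dual_network():
    """The worked alignment example: seven correspondence pairs v1–w1 …
    v7–w7 where (v1,v2)+(w1,w2) yield a Match, (v2,v3) has only the
    physical edge with a conceptual path of length 2, and v7/w7 are
    isolated in both layers."""
    phys = nx.Graph([("v1", "v2"), ("v2", "v3"), ("v3", "v4"), ("v4", "v5"), ("v5", "v6")])
    phys.add_node("v7")
    conc = nx.Graph()
    conc.add_node("w7")
    conc.add_weighted_edges_from(
        [("w1", "w2", 0.8), ("w2", "w4", 0.5), ("w3", "w4", 0.6),
         ("w4", "w5", 0.7), ("w5", "w6", 0.9)]
    )
    mapping = tuple((f"v{i}", f"w{i}") for i in range(1, 8))
    return assemble_dual_network(phys, conc, mapping)


def random_dual_network(seed, n_nodes=None, overlap_mode=None):
    """Small random dual network drawn through the synthetic generator with
    randomised spec parameters (used by the property tests)."""
    rng = np.random.default_rng(seed)
    n = int(n_nodes if n_nodes is not None else rng.integers(8, 30))
    mode = overlap_mode or ("overlapping" if rng.random() < 0.5 else "disjoint")
    k = int(rng.integers(2, 5))
    size_min = 2
    size_max = max(2, n // k if mode == "disjoint" else int(rng.integers(2, max(3, n // 2))))
    pairs = n * (n - 1) // 2
    spec = SyntheticSpec(
        n_nodes=n,
        n_communities=k,
        size_min=size_min,
        size_max=size_max,
        overlap_mode=mode,
        physical_edge_target=int(rng.integers(n // 2, min(3 * n, pairs))),
        conceptual_edge_target=int(rng.integers(n // 2, min(3 * n, pairs))),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return generate_dual_network(spec)


def random_weighted_graph(seed, max_nodes=12, weighted=True):
    """Random graph for the densest-subgraph property tests."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_nodes + 1))
    p = float(rng.uniform(0.2, 0.8))
    graph = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
    graph = nx.relabel_nodes(graph, {i: f"x{i:02d}" for i in graph.nodes})
    for u, v in graph.edges():
        graph[u][v]["weight"] = float(rng.uniform(0.1, 5.0)) if weighted else 1.0
    return graph
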