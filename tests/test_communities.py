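import networkx as nx
import pytest

import oracles
from dualnet import (
    Community,
    DualNetworkError,
    assemble_dual_network,
    detect_modular_communities,
    louvain_partition,
    modularity,
    refine_connectivity,
)
from conftest import random_weighted_graph


def two_cliques_with_bridge():
    g = nx.Graph()
    left = [f"a{i}" for i in range(4)]
    right = [f"b{i}" for i in range(4)]
    for block in (left, right):
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(block[i], block[j], weight=1.0)
    g.add_edge("a0", "b0", weight=1.0)
    return g, frozenset(left), frozenset(right)


class TestLouvain:
    def test_two_cliques_split_at_global_optimum(self):
        g, left, right = two_cliques_with_bridge()
        partition = louvain_partition(g, seed=0)
        assert set(partition.communities) == {left, right}
        best_q, _ = oracles.best_partition_exhaustive(g)
        assert partition.modularity == pytest.approx(best_q)

    def test_edgeless_graph_gives_singletons(self):
        g = nx.empty_graph(5)
        partition = louvain_partition(g, seed=0)
        assert len(partition.communities) == 5
        assert partition.modularity == 0.0

    def test_single_clique_stays_whole(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        partition = louvain_partition(g, seed=0)
        assert len(partition.communities) == 1
        _, best_blocks = oracles.best_partition_exhaustive(g)
        assert set(partition.communities) == set(best_blocks)

    def test_deterministic_under_seed(self):
        g = random_weighted_graph(3, max_nodes=20)
        runs = {louvain_partition(g, seed=11).communities for _ in range(3)}
        assert len(runs) == 1

    def test_empty_graph_rejected(self):
        with pytest.raises(DualNetworkError):
            louvain_partition(nx.Graph())

    def test_nonsingleton_partition_beats_singletons_when_edges_exist(self):
        g = random_weighted_graph(5)
        partition = louvain_partition(g, seed=1)
        assert partition.modularity >= 0.0


class TestModularity:
    def test_one_block_is_zero(self):
        g = random_weighted_graph(9)
        assert modularity(g, [set(g.nodes)]) == pytest.approx(0.0)

    def test_two_disjoint_triangles(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                          ("x", "y"), ("y", "z"), ("x", "z")])
        nx.set_edge_attributes(g, 1.0, "weight")
        q = modularity(g, [{"a", "b", "c"}, {"x", "y", "z"}])
        assert q == pytest.approx(0.5)

    def test_edgeless_graph_defined_as_zero(self):
        g = nx.empty_graph(4)
        assert modularity(g, [{n} for n in g.nodes]) == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_pairwise_oracle(self, seed):
        g = random_weighted_graph(seed, max_nodes=8)
        partition = louvain_partition(g, seed=seed).communities
        assert modularity(g, partition) == pytest.approx(
            oracles.modularity_naive(g, partition)
        )


def make_community(*phys_nodes):
    return Community.from_alignment_nodes({(n, n) for n in phys_nodes})


class TestRefineConnectivity:
    def test_connected_projection_unchanged(self):
        phys = nx.path_graph(["a", "b", "c"])
        refined = refine_connectivity(make_community("a", "b", "c"), phys)
        assert refined.physical_nodes == frozenset("abc")
        assert refined.connected_in_physical

    def test_largest_component_kept(self):
        phys = nx.Graph([("a", "b"), ("b", "c")])
        phys.add_node("d")
        refined = refine_connectivity(make_community("a", "b", "c", "d"), phys)
        assert refined.physical_nodes == frozenset("abc")

    def test_tie_breaks_on_conceptual_weight(self):
        phys = nx.Graph([("a", "b"), ("c", "d")])
        conc = nx.Graph()
        conc.add_weighted_edges_from([("a", "b", 1.0), ("c", "d", 3.0)])
        refined = refine_connectivity(make_community("a", "b", "c", "d"), phys, conc)
        assert refined.physical_nodes == frozenset("cd")

    def test_final_tie_break_lexicographic(self):
        phys = nx.Graph([("a", "b"), ("c", "d")])
        refined = refine_connectivity(make_community("a", "b", "c", "d"), phys)
        assert refined.physical_nodes == frozenset("ab")

    def test_fully_isolated_projection_returns_single_node(self):
        phys = nx.Graph()
        phys.add_nodes_from("abc")
        refined = refine_connectivity(make_community("a", "b", "c"), phys)
        assert len(refined) == 1 and refined.connected_in_physical

    @pytest.mark.parametrize("seed", range(10))
    def test_subset_and_idempotent(self, seed):
        from conftest import random_dual_network

        dn, _ = random_dual_network(seed)
        nodes = frozenset(list(dn.mapping)[: max(3, len(dn.mapping) // 2)])
        community = Community.from_alignment_nodes(nodes)
        once = refine_connectivity(community, dn.physical, dn.conceptual)
        assert once.alignment_nodes <= community.alignment_nodes
        twice = refine_connectivity(once, dn.physical, dn.conceptual)
        assert twice.alignment_nodes == once.alignment_nodes


class TestDetectModularCommunities:
    def planted_pair(self):
        """Two groups, dense within and absent between, identical layers."""
        phys = nx.Graph()
        conc = nx.Graph()
        groups = [frozenset(f"a{i}" for i in range(4)), frozenset(f"b{i}" for i in range(4))]
        for group in groups:
            members = sorted(group)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    phys.add_edge(members[i], members[j])
                    conc.add_edge(members[i], members[j], weight=1.0)
        return assemble_dual_network(phys, conc), groups

    def test_recovers_planted_groups(self):
        dn, groups = self.planted_pair()
        found = detect_modular_communities(dn, delta=1, seed=0, min_size=3)
        assert {c.physical_nodes for c in found} == set(groups)

    def test_every_projection_connected(self):
        from conftest import random_dual_network

        for seed in range(10):
            dn, _ = random_dual_network(seed)
            for community in detect_modular_communities(dn, delta=2, seed=seed, min_size=2):
                sub = dn.physical.subgraph(community.physical_nodes)
                assert nx.is_connected(sub)

    def test_empty_conceptual_layer_yields_no_communities(self):
        phys = nx.path_graph(["a", "b", "c"])
        conc = nx.Graph()
        conc.add_nodes_from("abc")
        dn = assemble_dual_network(phys, conc)
        assert detect_modular_communities(dn, min_size=2) == []

    def test_physically_split_community_is_reduced(self):
        # conceptually one clique, physically two components
        conc = nx.Graph()
        members = ["a", "b", "c", "d"]
        for i in range(4):
            for j in range(i + 1, 4):
                conc.add_edge(members[i], members[j], weight=1.0)
        phys = nx.Graph([("a", "b"), ("c", "d")])
        dn = assemble_dual_network(phys, conc)
        found = detect_modular_communities(dn, delta=2, seed=0, min_size=2)
        assert found  # something survives
        for com in found:
            # no community spans the physical split
            assert com.physical_nodes <= frozenset("ab") or com.physical_nodes <= frozenset("cd")
            assert nx.is_connected(phys.subgraph(com.physical_nodes))

    def test_sorted_by_modularity_contribution(self):
        from conftest import random_dual_network

        dn, _ = random_dual_network(4)
        found = detect_modular_communities(dn, delta=2, seed=4, min_size=2)
        contributions = [c.modularity_contribution for c in found]
        assert contributions == sorted(contributions, reverse=True)

    def test_deterministic(self):
        dn, groups = self.planted_pair()
        runs = [detect_modular_communities(dn, seed=5) for _ in range(2)]
        assert [c.alignment_nodes for c in runs[0]] == [c.alignment_nodes for c in runs[1]]
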