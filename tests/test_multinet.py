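"""Multilayer assembly: expansion, merging, centralities, container rules."""

import math

import networkx as nx
import numpy as np
import pytest

from netcontrol import multinet, synthdata
from netcontrol.network import Edge, Node, NetworkError, TypedNetwork

from conftest import make_network


class TestContainer:
    def test_rejects_self_loop(self):
        net = TypedNetwork()
        net.add_node(Node("a", "gene"))
        with pytest.raises(NetworkError, match="self-loop"):
            net.add_edge(Edge("a", "a", "coexpression", directed=False))

    def test_rejects_duplicate_edge_either_orientation(self):
        net = make_network(undirected=[("a", "b", "ppi")])
        with pytest.raises(NetworkError, match="duplicate"):
            net.add_edge(Edge("b", "a", "ppi", directed=False))

    def test_rejects_dangling_endpoint(self):
        net = TypedNetwork()
        net.add_node(Node("a", "gene"))
        with pytest.raises(NetworkError, match="not in node set"):
            net.add_edge(Edge("a", "zzz", "coexpression", directed=False))

    def test_layer_direction_rules(self):
        net = make_network(directed=[("m", "g", "mirna_target")])
        with pytest.raises(NetworkError, match="directed"):
            net.add_edge(Edge("m", "g", "ppi", directed=True))

    def test_same_pair_multiple_layers_allowed(self):
        net = make_network(
            undirected=[("a", "b", "coexpression")],
            kinds={"a": "gene", "b": "gene"},
        )
        net.add_edge(Edge("a", "b", "ppi", directed=False))
        assert net.n_edges() == 2


class TestExpandFirstOrder:
    def test_isolated_seed(self):
        ref = make_network(undirected=[("x", "y", "ppi")])
        with pytest.warns(UserWarning, match="isolated"):
            out = multinet.expand_first_order(["lonely"], ref)
        assert out.node_ids() == ["lonely"]
        assert out.n_edges() == 0

    def test_neighbor_neighbor_edge_retained(self):
        ref = make_network(
            undirected=[("s", "a", "ppi"), ("s", "b", "ppi"), ("a", "b", "ppi")]
        )
        out = multinet.expand_first_order(["s"], ref)
        assert out.n_nodes() == 3
        assert out.n_edges() == 3

    def test_counts_match_bfs_depth_one_oracle(self):
        interactome = synthdata.simulate_interactome(2000, 2, seed=13)
        rng = np.random.default_rng(4)
        seeds = [f"P{i:04d}" for i in rng.choice(2000, size=20, replace=False)]
        out = multinet.expand_first_order(seeds, interactome)
        g = interactome.to_undirected_nx()
        expected_nodes = set(seeds)
        for s in seeds:
            expected_nodes |= set(
                nx.single_source_shortest_path_length(g, s, cutoff=1)
            )
        assert set(out.node_ids()) == expected_nodes
        expected_edges = sum(
            1 for u, v in g.edges if u in expected_nodes and v in expected_nodes
        )
        assert out.n_edges() == expected_edges

    def test_expansion_monotone_in_seeds(self):
        interactome = synthdata.simulate_interactome(300, 2, seed=3)
        small = multinet.expand_first_order(["P0005"], interactome)
        large = multinet.expand_first_order(["P0005", "P0017"], interactome)
        assert set(small.node_ids()) <= set(large.node_ids())
        assert {e.key() for e in small} <= {e.key() for e in large}

    def test_empty_seed_list_rejected(self):
        ref = make_network(undirected=[("x", "y", "ppi")])
        with pytest.raises(ValueError):
            multinet.expand_first_order([], ref)


class TestMergeLayers:
    def test_disjoint_layers_sum(self):
        a = make_network(undirected=[("g1", "g2", "coexpression")])
        b = make_network(directed=[("m1", "g9", "mirna_target")])
        merged = multinet.merge_layers([a, b])
        assert merged.n_nodes() == 4
        assert merged.n_edges() == 2

    def test_same_pair_two_layers_keeps_both_edges(self):
        a = make_network(undirected=[("x", "y", "coexpression")])
        b = make_network(undirected=[("x", "y", "ppi")],
                         kinds={"x": "gene", "y": "gene"})
        merged = multinet.merge_layers([a, b])
        assert merged.n_nodes() == 2
        assert merged.n_edges() == 2

    def test_three_layer_hand_tally(self):
        coexpr = make_network(
            undirected=[("g1", "g2", "coexpression"), ("g2", "g3", "coexpression")]
        )
        ppi = make_network(
            undirected=[("g1", "g2", "ppi"), ("g3", "g4", "ppi")],
            kinds={"g1": "gene", "g2": "gene", "g3": "gene", "g4": "gene"},
        )
        mir = make_network(directed=[("m1", "g1", "mirna_target"),
                                     ("m1", "g4", "mirna_target")])
        merged = multinet.merge_layers([coexpr, ppi, mir])
        # nodes: g1..g4, m1; edges: 2 + 2 + 2
        assert merged.n_nodes() == 5
        assert merged.n_edges() == 6

    def test_annotation_priority_up_over_none(self):
        a = make_network(undirected=[("g1", "g2", "coexpression")])
        a.nodes["g1"].de_status = "up"
        b = make_network(undirected=[("g1", "g3", "coexpression")])
        merged = multinet.merge_layers([b, a])
        assert merged.nodes["g1"].de_status == "up"

    def test_gene_protein_same_entity(self):
        a = make_network(undirected=[("g1", "g2", "coexpression")])
        b = make_network(undirected=[("g1", "g3", "ppi")])
        merged = multinet.merge_layers([a, b])
        assert merged.n_nodes() == 3

    def test_kind_collision_rejected(self):
        a = make_network(directed=[("x", "g1", "mirna_target")])
        b = make_network(directed=[("x", "g2", "drug_gene")])
        with pytest.raises(NetworkError, match="collision"):
            multinet.merge_layers([a, b])

    def test_merge_idempotent(self):
        a = make_network(undirected=[("g1", "g2", "coexpression")])
        b = make_network(directed=[("m1", "g1", "mirna_target")])
        once = multinet.merge_layers([a, b])
        twice = multinet.merge_layers([once, b])
        assert {e.key() for e in once} == {e.key() for e in twice}
        assert set(once.node_ids()) == set(twice.node_ids())

    def test_degree_sum_is_twice_edge_count_per_layer(self):
        interactome = synthdata.simulate_interactome(100, 2, seed=9)
        g = interactome.to_undirected_nx(layers=["ppi"])
        assert sum(d for _, d in g.degree()) == 2 * interactome.n_edges()


class TestCentralities:
    def test_star_closed_forms(self):
        k = 6
        net = make_network(
            undirected=[("hub", f"leaf{i}", "ppi") for i in range(k)]
        )
        table = multinet.centralities(net)
        assert table.loc["hub", "betweenness"] == pytest.approx(k * (k - 1) / 2)
        assert table.loc["hub", "clustering"] == 0.0
        assert table.loc["hub", "degree"] == k

    def test_triangle_closed_forms(self):
        net = make_network(
            undirected=[("a", "b", "ppi"), ("b", "c", "ppi"), ("a", "c", "ppi")]
        )
        table = multinet.centralities(net)
        assert table.loc["a", "clustering"] == 1.0
        assert table.loc["a", "mcc"] == math.factorial(2)

    def test_matches_brute_force_on_random_graph(self):
        rng = np.random.default_rng(31)
        g = nx.gnp_random_graph(12, 0.35, seed=7)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g})
        net = make_network(undirected=[(u, v, "ppi") for u, v in g.edges])
        table = multinet.centralities(net)
        # brute force betweenness: enumerate all shortest paths per pair
        for v in g.nodes:
            acc = 0.0
            for s in g.nodes:
                for t in g.nodes:
                    if s >= t or v in (s, t):
                        continue
                    try:
                        paths = list(nx.all_shortest_paths(g, s, t))
                    except nx.NetworkXNoPath:
                        continue
                    acc += sum(1 for p in paths if v in p[1:-1]) / len(paths)
            assert table.loc[v, "betweenness"] == pytest.approx(acc)
        # brute force clustering and MCC
        for v in g.nodes:
            nbrs = list(g.neighbors(v))
            d = len(nbrs)
            links = sum(
                1 for i in range(d) for j in range(i + 1, d)
                if g.has_edge(nbrs[i], nbrs[j])
            )
            expected_c = 2 * links / (d * (d - 1)) if d > 1 else 0.0
            assert table.loc[v, "clustering"] == pytest.approx(expected_c)
            mcc = sum(
                math.factorial(len(c) - 1)
                for c in nx.find_cliques(g) if v in c
            )
            assert table.loc[v, "mcc"] == mcc
        del rng

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            multinet.centralities(TypedNetwork())
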