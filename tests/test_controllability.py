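"""Structural controllability: matching framework, MDS mode, Kalman rank.

Every classification is checked against an exhaustive oracle on random small
instances, and the analytic fixtures are verified against hand enumeration.
"""

import networkx as nx
import numpy as np
import pytest
import sympy

from netcontrol import controllability as ctrl
from netcontrol.network import Edge, Node, TypedNetwork

from conftest import make_network, random_digraph


def digraph(*arcs):
    g = nx.DiGraph()
    g.add_edges_from(arcs)
    return g


class TestDirectedView:
    def test_undirected_edge_becomes_antiparallel_pair(self):
        net = make_network(undirected=[("a", "b", "ppi")])
        g = ctrl.directed_view(net)
        assert set(g.edges) == {("a", "b"), ("b", "a")}

    def test_directed_edge_kept_as_is(self):
        net = make_network(directed=[("m", "g", "mirna_target")])
        g = ctrl.directed_view(net)
        assert set(g.edges) == {("m", "g")}

    def test_mixed_arc_count(self):
        net = make_network(
            undirected=[("a", "b", "ppi"), ("b", "c", "coexpression")],
            directed=[("m", "a", "mirna_target"), ("d", "b", "drug_gene")],
        )
        g = ctrl.directed_view(net)
        assert g.number_of_edges() == 2 + 2 * 2


class TestDriverAnalysis:
    def test_isolated_nodes_all_drivers(self):
        g = nx.DiGraph()
        g.add_nodes_from("abcd")
        r = ctrl.driver_analysis(g)
        assert r.n_d == 4
        assert r.representative_set == {"a", "b", "c", "d"}

    def test_directed_path_single_driver(self):
        r = ctrl.driver_analysis(digraph(("1", "2"), ("2", "3")))
        assert r.n_d == 1
        assert r.representative_set == {"1"}

    def test_two_cycle_floor_convention(self):
        r = ctrl.driver_analysis(digraph(("1", "2"), ("2", "1")))
        assert r.n_d == 1
        assert len(r.representative_set) == 1

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            ctrl.driver_analysis(nx.DiGraph())

    def test_nd_independent_of_node_labels(self):
        """N - mu is matching-invariant: relabeling (hence reordering) nodes
        never changes the driver count."""
        rng = np.random.default_rng(55)
        for _ in range(5):
            g = random_digraph(rng)
            base = ctrl.driver_analysis(g).n_d
            perm = list(g.nodes)
            rng.shuffle(perm)
            h = nx.relabel_nodes(g, dict(zip(sorted(g.nodes), perm)))
            assert ctrl.driver_analysis(h).n_d == base


class TestNodeClasses:
    def test_path_classes(self):
        classes = ctrl.classify_nodes(digraph(("1", "2"), ("2", "3")))
        assert classes == {"1": "critical", "2": "redundant", "3": "redundant"}

    def test_star_classes(self):
        classes = ctrl.classify_nodes(digraph(("h", "a"), ("h", "b")))
        assert classes == {"h": "critical", "a": "intermittent",
                           "b": "intermittent"}

    def test_perfect_matching_all_intermittent(self):
        classes = ctrl.classify_nodes(digraph(("1", "2"), ("2", "1")))
        assert set(classes.values()) == {"intermittent"}

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(101)
        checked = 0
        while checked < 30:
            g = random_digraph(rng)
            nd, node_ref, _ = ctrl.oracle_classes(g)
            assert ctrl.driver_analysis(g).n_d == nd
            assert ctrl.classify_nodes(g) == node_ref
            checked += 1

    def test_classes_partition_node_set(self):
        rng = np.random.default_rng(7)
        g = random_digraph(rng, n_max=9)
        classes = ctrl.classify_nodes(g)
        assert set(classes) == set(g.nodes)
        assert set(classes.values()) <= {"critical", "intermittent", "redundant"}


class TestLinkClasses:
    def test_path_links_critical(self):
        classes = ctrl.classify_links(digraph(("1", "2"), ("2", "3")))
        assert classes == {("1", "2"): "critical", ("2", "3"): "critical"}

    def test_star_links_ordinary(self):
        classes = ctrl.classify_links(digraph(("h", "a"), ("h", "b")))
        assert classes == {("h", "a"): "ordinary", ("h", "b"): "ordinary"}

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(202)
        checked = 0
        while checked < 30:
            g = random_digraph(rng)
            if g.number_of_edges() == 0:
                continue
            _, _, link_ref = ctrl.oracle_classes(g)
            assert ctrl.classify_links(g) == link_ref
            checked += 1

    def test_undirected_edge_inherits_more_critical_class(self):
        net = make_network(undirected=[("a", "b", "ppi")])
        g = ctrl.directed_view(net)
        arc_classes = ctrl.classify_links(g)
        merged = ctrl.undirected_link_classes(net, arc_classes)
        (key, cls), = merged.items()
        order = {"critical": 0, "ordinary": 1, "redundant": 2}
        assert order[cls] == min(
            order[arc_classes[("a", "b")]], order[arc_classes[("b", "a")]]
        )

    def test_critical_link_endpoints_promoted(self):
        link_class = {("a", "b", "ppi"): "critical", ("b", "c", "ppi"): "ordinary"}
        node_class = {"a": "intermittent", "b": "redundant", "c": "redundant"}
        out = ctrl.critical_nodes_from_links(link_class, node_class)
        assert out["a"] == "critical" and out["b"] == "critical"
        assert out["c"] == "redundant"


class TestEnumerationOracle:
    def test_path_has_unique_maximum_matching(self):
        m = ctrl.enumerate_matchings_oracle(digraph(("1", "2"), ("2", "3")))
        assert m == [frozenset({("1", "2"), ("2", "3")})]

    def test_star_has_two(self):
        m = ctrl.enumerate_matchings_oracle(digraph(("h", "a"), ("h", "b")))
        assert len(m) == 2

    def test_edgeless_graph_single_empty_matching(self):
        g = nx.DiGraph()
        g.add_nodes_from("ab")
        assert ctrl.enumerate_matchings_oracle(g) == [frozenset()]

    def test_size_guard(self):
        g = nx.complete_graph(7, create_using=nx.DiGraph)
        with pytest.raises(ValueError, match="guard"):
            ctrl.enumerate_matchings_oracle(g)


class TestMDS:
    def test_star_hub_critical_leaves_redundant(self):
        g = nx.star_graph(4)
        r = ctrl.mds_analysis(g)
        assert r.n_d == 1
        assert r.node_class[0] == "critical"
        assert all(r.node_class[i] == "redundant" for i in range(1, 5))

    def test_single_edge_both_intermittent(self):
        g = nx.Graph([("a", "b")])
        r = ctrl.mds_analysis(g)
        assert r.n_d == 1
        assert set(r.node_class.values()) == {"intermittent"}

    def test_matches_subset_enumeration_oracle(self):
        rng = np.random.default_rng(303)
        for _ in range(30):
            n = int(rng.integers(2, 13))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.15, 0.5)),
                                    seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g})
            gamma_ref, class_ref = ctrl.mds_oracle(g)
            r = ctrl.mds_analysis(g)
            assert r.n_d == gamma_ref
            assert r.node_class == class_ref
            assert len(r.representative_set) == gamma_ref

    def test_exact_limit_guard(self):
        g = nx.path_graph(60)
        with pytest.raises(ValueError, match="exact-solver limit"):
            ctrl.mds_analysis(g)


class TestKalman:
    def test_zero_dynamics_identity_inputs(self):
        system = ctrl.KalmanSystem(sympy.zeros(2, 2), sympy.eye(2))
        assert ctrl.kalman_rank(system) == (2, True)

    def test_chain_controlled_from_head(self):
        a = sympy.zeros(3, 3)
        a[1, 0] = 1
        a[2, 1] = 1
        b = sympy.Matrix([[1], [0], [0]])
        assert ctrl.kalman_rank(ctrl.KalmanSystem(a, b)) == (3, True)

    def test_chain_uncontrollable_from_tail(self):
        a = sympy.zeros(3, 3)
        a[1, 0] = 1
        a[2, 1] = 1
        b = sympy.Matrix([[0], [0], [1]])
        rank, ok = ctrl.kalman_rank(ctrl.KalmanSystem(a, b))
        assert rank == 1 and not ok

    def test_b_columns_must_be_unit_basis(self):
        with pytest.raises(ValueError, match="unit basis"):
            ctrl.KalmanSystem(sympy.zeros(2, 2), sympy.Matrix([[1], [1]]))

    def test_size_cap(self):
        n = ctrl.KALMAN_EXACT_LIMIT + 1
        with pytest.raises(ValueError, match="exact"):
            ctrl.kalman_rank(ctrl.KalmanSystem(sympy.zeros(n, n), sympy.eye(n)))

    def test_input_placement_generically_controllable(self):
        """Random integer weights on the arcs with B = the identified input
        set (drivers plus accessibility completion) give full Kalman rank in
        >= 95% of draws: structural controllability holds generically."""
        rng = np.random.default_rng(404)
        ok = 0
        total = 50
        for _ in range(total):
            g = random_digraph(rng, n_max=8, max_arcs=100)
            inputs = ctrl.controllable_input_set(g)
            system = ctrl.system_from_graph(g, inputs, rng)
            _, controllable = ctrl.kalman_rank(system)
            ok += controllable
        assert ok / total >= 0.95

    def test_accessibility_completion_covers_source_cycles(self):
        """A 2-cycle feeding nothing is unreachable from the path's driver;
        the input set adds one of its members."""
        g = digraph(("1", "2"), ("a", "b"), ("b", "a"))
        drivers = ctrl.driver_analysis(g).representative_set
        inputs = ctrl.controllable_input_set(g)
        assert drivers == {"1"}
        assert inputs == {"1", "a"}
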