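"""Shared fixtures: small synthetic inputs generated at test time."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

from netcontrol.catalog import ComplexCatalog
from netcontrol.network import Edge, Node, TypedNetwork
from netcontrol.synthdata import ExpressionMatrix, simulate_expression


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """500-gene, 20-per-group matrix with 10% planted effects of 2.0 log2
    units at noise sd 0.5 (the default study conditions)."""
    expr, _ = simulate_expression(
        n_genes=500, n_per_group=20, de_fraction=0.1,
        effect_log2fc=2.0, noise_sd=0.5, seed=11,
    )
    return expr


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """Hand-sized 4-gene matrix for exact-arithmetic checks."""
    rng = np.random.default_rng(5)
    values = rng.normal(8.0, 1.0, size=(4, 6))
    return ExpressionMatrix(
        values=values,
        gene_ids=["g1", "g2", "g3", "g4"],
        sample_ids=["a1", "a2", "a3", "b1", "b2", "b3"],
        group_of={"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"},
    )


def make_network(undirected=(), directed=(), kinds=None) -> TypedNetwork:
    """Build a TypedNetwork from edge tuples (source, target, layer)."""
    kinds = kinds or {}
    net = TypedNetwork()
    default_kind = {
        "coexpression": ("gene", "gene"),
        "ppi": ("protein", "protein"),
        "mirna_target": ("mirna", "gene"),
        "drug_gene": ("drug", "gene"),
    }
    for s, t, layer in list(undirected) + list(directed):
        sk, tk = default_kind[layer]
        for nid, kind in ((s, sk), (t, tk)):
            if nid not in net.nodes:
                net.add_node(Node(nid, kinds.get(nid, kind)))
    for s, t, layer in undirected:
        net.add_edge(Edge(s, t, layer, directed=False))
    for s, t, layer in directed:
        net.add_edge(Edge(s, t, layer, directed=True))
    return net


@pytest.fixture
def ppi_triangle_net() -> TypedNetwork:
    return make_network(
        undirected=[("a", "b", "ppi"), ("b", "c", "ppi"), ("a", "c", "ppi"),
                    ("c", "d", "ppi")]
    )


@pytest.fixture
def toy_catalog() -> ComplexCatalog:
    return ComplexCatalog(
        {
            "CPX-A": {"a", "b", "c"},
            "CPX-B": {"c", "d", "e"},
            "CPX-C": {"x", "y"},
        }
    )


def random_digraph(rng: np.random.Generator, n_max: int = 9,
                   max_arcs: int = 25) -> nx.DiGraph:
    """Small random digraph for oracle comparisons; arc count guarded."""
    while True:
        n = int(rng.integers(2, n_max + 1))
        p = float(rng.uniform(0.1, 0.5))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)), directed=True)
        if g.number_of_edges() <= max_arcs:
            return nx.relabel_nodes(g, {i: f"n{i}" for i in g})
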