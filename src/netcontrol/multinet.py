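"""Multilayer network assembly and topological profiling.

First-order interactome expansion around seed genes, layer merging with
annotation reconciliation, and the hub-analysis centralities (degree,
betweenness, clustering, maximal-clique centrality).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import replace

import networkx as nx
import pandas as pd

from .network import Edge, Node, NetworkError, TypedNetwork, merge_annotations


def expand_first_order(seed_ids: list[str], reference: TypedNetwork) -> TypedNetwork:
    """Induced subgraph over the seeds plus their direct interactome neighbors.

    All reference edges with both endpoints inside that node set are kept, so
    neighbor–neighbor links (and therefore sub-complex connectivity) survive.
    Seeds absent from the reference remain as isolated nodes.
    """
    if not seed_ids:
        raise ValueError("seed list must be nonempty")
    g = reference.to_undirected_nx()
    keep: set[str] = set()
    missing: list[str] = []
    for s in seed_ids:
        keep.add(s)
        if s in g:
            keep.update(g.neighbors(s))
        elif s not in reference.nodes:
            missing.append(s)
    if missing:
        warnings.warn(
            f"{len(missing)} seed(s) absent from reference kept as isolated nodes",
            stacklevel=2,
        )
    out = TypedNetwork()
    for nid in sorted(keep):
        if nid in reference.nodes:
            out.add_node(replace(reference.nodes[nid]))
        else:
            out.add_node(Node(nid, "protein"))
    for edge in reference:
        if edge.source in keep and edge.target in keep:
            out.add_edge(edge)
    return out


def merge_layers(networks: list[TypedNetwork]) -> TypedNetwork:
    """Union of nodes and layer-keyed edges.

    Node annotations are reconciled (up/down outranks none; mutation flags OR;
    the gene/protein kind pair is one entity). The same node pair may carry
    one edge per layer.
    """
    out = TypedNetwork()
    seen: set[tuple[str, str, str]] = set()
    for net in networks:
        for node in net.nodes.values():
            if node.id in out.nodes:
                out.nodes[node.id] = merge_annotations(out.nodes[node.id], node)
            else:
                out.add_node(replace(node))
        for edge in net:
            if edge.key() not in seen:
                out.add_edge(edge)
                seen.add(edge.key())
    return out


def annotate_de(net: TypedNetwork, direction_of: dict[str, str]) -> TypedNetwork:
    """Return a copy with de_status set from a gene -> {up,down} map."""
    out = net.copy()
    for gid, direction in direction_of.items():
        if gid in out.nodes:
            out.nodes[gid].de_status = direction
    return out


def maximal_clique_centrality(g: nx.Graph) -> dict[str, int]:
    """MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!."""
    mcc = {v: 0 for v in g.nodes}
    for clique in nx.find_cliques(g):
        w = math.factorial(len(clique) - 1)
        for v in clique:
            mcc[v] += w
    return mcc


def centralities(network: TypedNetwork) -> pd.DataFrame:
    """Degree, unnormalized shortest-path betweenness, local clustering, and
    maximal-clique centrality on the simple undirected view."""
    if network.n_nodes() == 0:
        raise ValueError("network must be nonempty")
    g = network.to_undirected_nx()
    bc = nx.betweenness_centrality(g, normalized=False)
    cc = nx.clustering(g)
    mcc = maximal_clique_centrality(g)
    rows = [
        dict(
            node=v,
            degree=g.degree(v),
            betweenness=float(bc[v]),
            clustering=float(cc[v]),
            mcc=int(mcc[v]),
        )
        for v in sorted(g.nodes)
    ]
    return pd.DataFrame(rows).set_index("node")
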