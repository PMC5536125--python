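"""Typed multilayer network container.

Nodes carry a molecular kind (gene, miRNA, protein, drug) and analysis
annotations (differential-expression status, mutation flag). Edges live in
one of four layers; miRNA->target and drug->gene layers are directed,
co-expression and physical protein interaction layers are undirected.
Edge identity is the (source, target, layer) triple, so the same node pair
may be linked in several layers at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import networkx as nx

NODE_KINDS = frozenset({"gene", "mirna", "protein", "drug"})
LAYERS = frozenset({"coexpression", "mirna_target", "ppi", "drug_gene"})
DIRECTED_LAYERS = frozenset({"mirna_target", "drug_gene"})
DE_STATUSES = frozenset({"up", "down", "none"})


class NetworkError(ValueError):
    """Raised when a network invariant is violated."""


@dataclass
class Node:
    id: str
    kind: str
    de_status: str = "none"
    mutated: bool = False

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise NetworkError(f"unknown node kind {self.kind!r} for {self.id!r}")
        if self.de_status not in DE_STATUSES:
            raise NetworkError(f"unknown de_status {self.de_status!r} for {self.id!r}")


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    layer: str
    directed: bool
    weight: Optional[float] = None

    def key(self) -> tuple[str, str, str]:
        """Identity triple; undirected edges are canonicalized by sorted endpoints."""
        if self.directed:
            return (self.source, self.target, self.layer)
        a, b = sorted((self.source, self.target))
        return (a, b, self.layer)


class TypedNetwork:
    """Multitype, multilayer graph with per-edge direction and weight."""

    def __init__(self) -> None:
        self.nodes: dict[str, Node] = {}
        self._edges: dict[tuple[str, str, str], Edge] = {}

    # -- construction -------------------------------------------------

    def add_node(self, node: Node) -> None:
        existing = self.nodes.get(node.id)
        if existing is not None and existing.kind != node.kind:
            raise NetworkError(
                f"id collision: {node.id!r} is both {existing.kind} and {node.kind}"
            )
        if existing is None:
            self.nodes[node.id] = node

    def add_edge(self, edge: Edge) -> None:
        if edge.layer not in LAYERS:
            raise NetworkError(f"unknown layer {edge.layer!r}")
        expected_directed = edge.layer in DIRECTED_LAYERS
        if edge.directed != expected_directed:
            raise NetworkError(
                f"layer {edge.layer!r} must be "
                f"{'directed' if expected_directed else 'undirected'}"
            )
        if edge.source == edge.target:
            raise NetworkError(f"self-loop on {edge.source!r} rejected")
        for end in (edge.source, edge.target):
            if end not in self.nodes:
                raise NetworkError(f"edge endpoint {end!r} not in node set")
        key = edge.key()
        if key in self._edges:
            raise NetworkError(f"duplicate edge {key}")
        self._edges[key] = edge

    # -- access -------------------------------------------------------

    @property
    def edges(self) -> list[Edge]:
        return list(self._edges.values())

    def has_edge(self, source: str, target: str, layer: str) -> bool:
        directed = layer in DIRECTED_LAYERS
        probe = Edge(source, target, layer, directed)
        return probe.key() in self._edges

    def n_nodes(self) -> int:
        return len(self.nodes)

    def n_edges(self) -> int:
        return len(self._edges)

    def layers_present(self) -> set[str]:
        return {e.layer for e in self._edges.values()}

    def node_ids(self) -> list[str]:
        return sorted(self.nodes)

    def copy(self) -> "TypedNetwork":
        out = TypedNetwork()
        for node in self.nodes.values():
            out.add_node(replace(node))
        for edge in self._edges.values():
            out.add_edge(edge)
        return out

    # -- conversions ---------------------------------------------------

    def to_undirected_nx(self, layers: Optional[Iterable[str]] = None) -> nx.Graph:
        """Simple undirected view; parallel inter-layer edges collapse to one."""
        wanted = set(layers) if layers is not None else None
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for edge in self._edges.values():
            if wanted is not None and edge.layer not in wanted:
                continue
            attrs = {"layer": edge.layer}
            if edge.weight is not None:
                attrs["weight"] = edge.weight
            g.add_edge(edge.source, edge.target, **attrs)
        if wanted is not None:
            keep = {n for e in g.edges for n in e}
            # retain nodes of the requested layers only when filtering
            g.remove_nodes_from([n for n in list(g.nodes) if n not in keep])
        return g

    def subgraph(self, node_ids: Iterable[str]) -> "TypedNetwork":
        keep = set(node_ids)
        out = TypedNetwork()
        for nid in sorted(keep):
            if nid in self.nodes:
                out.add_node(replace(self.nodes[nid]))
        for edge in self._edges.values():
            if edge.source in keep and edge.target in keep:
                out.add_edge(edge)
        return out

    def __iter__(self) -> Iterator[Edge]:
        return iter(self._edges.values())

    def __repr__(self) -> str:
        return (
            f"TypedNetwork(n_nodes={self.n_nodes()}, n_edges={self.n_edges()}, "
            f"layers={sorted(self.layers_present())})"
        )


def merge_annotations(base: Node, other: Node) -> Node:
    """Merge two records of the same entity; up/down outranks none, mutated is OR.

    A gene and its protein product share one id: the gene/protein kind pair is
    compatible and resolves to the kind of the record seen first. Any other
    kind mismatch is an id collision.
    """
    if base.id != other.id:
        raise NetworkError("cannot merge annotations across different ids")
    if base.kind != other.kind and {base.kind, other.kind} != {"gene", "protein"}:
        raise NetworkError(
            f"id collision: {base.id!r} is both {base.kind} and {other.kind}"
        )
    de = base.de_status if base.de_status != "none" else other.de_status
    return Node(base.id, base.kind, de_status=de, mutated=base.mutated or other.mutated)
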