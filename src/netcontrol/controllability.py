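"""Structural controllability of directed network views.

The linear time-invariant reading dx/dt = Ax + Bu makes a network
controllable when the Kalman matrix C = [B, AB, ..., A^(N-1)B] has full rank.
Structurally, the minimum number of driver nodes N_D equals N minus the size
of a maximum matching of the bipartite lift of the digraph (one out-copy and
one in-copy per node; arc u->v becomes lift edge u_out–v_in), floored at 1.

Node classes follow the minimal-configuration taxonomy: a node is *critical*
when it appears in every minimum driver set (its in-copy is matched in no
maximum matching), *redundant* when it appears in none (in-copy matched in
every maximum matching), and *intermittent* otherwise. Links are *critical*
when used by every maximum matching (removal raises N_D), *redundant* when
used by none, *ordinary* otherwise.

An alternative reading via minimum dominating sets (MDS) is provided behind
the same interface: gamma is the domination number and the same three node
classes are defined over the family of all MDSs.

Small-instance exhaustive oracles (matching enumeration, MDS subset search
implied by the branch-and-bound with forced/forbidden nodes) keep every
classification testable against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import networkx as nx
import numpy as np
import sympy

from .network import TypedNetwork

KALMAN_EXACT_LIMIT = 12
MDS_EXACT_LIMIT = 40

_NODE_CLASS_ORDER = {"critical": 0, "intermittent": 1, "redundant": 2}
_LINK_CLASS_ORDER = {"critical": 0, "ordinary": 1, "redundant": 2}


@dataclass
class ControllabilityResult:
    mode: str                                   # "matching" or "mds"
    n_d: int                                    # N_D, or domination number gamma
    representative_set: set[str]
    node_class: dict[str, str] = field(default_factory=dict)
    link_class: dict[tuple[str, str], str] = field(default_factory=dict)

    def class_counts(self) -> dict[str, int]:
        counts = {"critical": 0, "intermittent": 0, "redundant": 0}
        for c in self.node_class.values():
            counts[c] += 1
        return counts


# ---------------------------------------------------------------------------
# directed view and bipartite lift


def directed_view(network: TypedNetwork) -> nx.DiGraph:
    """Directed arcs kept as-is; each undirected edge becomes an antiparallel
    pair. Arc attribute ``layer`` records provenance."""
    if network.n_nodes() == 0:
        raise ValueError("network must be nonempty")
    g = nx.DiGraph()
    g.add_nodes_from(sorted(network.nodes))
    for edge in network:
        if edge.directed:
            g.add_edge(edge.source, edge.target, layer=edge.layer)
        else:
            g.add_edge(edge.source, edge.target, layer=edge.layer)
            g.add_edge(edge.target, edge.source, layer=edge.layer)
    return g


class _Lift:
    """Bipartite lift in index form: out-copy of node u is row u, in-copy of
    node v is column v, one entry per arc. Maximum matchings are computed by
    Hopcroft–Karp on the sparse matrix; deterministic for a fixed node order
    (lexicographic)."""

    def __init__(self, g: nx.DiGraph) -> None:
        from scipy.sparse import csr_matrix

        self.nodes = sorted(g.nodes)
        self.index = {v: i for i, v in enumerate(self.nodes)}
        self.arcs = [(self.index[u], self.index[v]) for u, v in sorted(g.edges)]
        self.n = len(self.nodes)
        self._csr = csr_matrix

    def matching_columns(
        self,
        skip_arc: Optional[tuple[int, int]] = None,
        skip_out: Optional[int] = None,
        skip_in: Optional[int] = None,
    ) -> "np.ndarray":
        """Row matched to each in-copy (-1 when unmatched), with an optional
        arc, out-copy, or in-copy deleted."""
        from scipy.sparse.csgraph import maximum_bipartite_matching

        rows, cols = [], []
        for u, v in self.arcs:
            if (u, v) == skip_arc or u == skip_out or v == skip_in:
                continue
            rows.append(u)
            cols.append(v)
        m = self._csr(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)),
            shape=(self.n, self.n),
        )
        return maximum_bipartite_matching(m, perm_type="row")

    def matching_size(self, **kwargs) -> int:
        return int((self.matching_columns(**kwargs) >= 0).sum())


def driver_analysis(g: nx.DiGraph) -> ControllabilityResult:
    """Minimum driver count and one representative driver set.

    N_D = max(N - mu, 1); the representative drivers are the nodes whose
    in-copy is unmatched under the deterministic maximum matching (or the
    lexicographically first node when the matching is perfect).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph must be nonempty")
    lift = _Lift(g)
    cols = lift.matching_columns()
    mu = int((cols >= 0).sum())
    unmatched = [lift.nodes[i] for i in range(lift.n) if cols[i] < 0]
    drivers = set(unmatched) if unmatched else {lift.nodes[0]}
    return ControllabilityResult(
        mode="matching", n_d=max(lift.n - mu, 1), representative_set=drivers
    )


def classify_nodes(g: nx.DiGraph) -> dict[str, str]:
    """Partition nodes into critical / intermittent / redundant driver roles."""
    if g.number_of_nodes() == 0:
        raise ValueError("graph must be nonempty")
    lift = _Lift(g)
    cols = lift.matching_columns()
    mu = int((cols >= 0).sum())
    if mu == lift.n:
        # perfect matching: any single node can host the one required input
        return {v: "intermittent" for v in lift.nodes}
    in_arcs: dict[int, list[int]] = {}
    for u, v in lift.arcs:
        in_arcs.setdefault(v, []).append(u)
    classes: dict[str, str] = {}
    for i, v in enumerate(lift.nodes):
        if cols[i] >= 0:
            # matched in the base matching, hence in SOME maximum matching;
            # redundant iff matched in every one
            always = lift.matching_size(skip_in=i) == mu - 1
            classes[v] = "redundant" if always else "intermittent"
            continue
        # unmatched in the base matching, hence a driver in SOME minimum set;
        # critical iff no in-arc can be forced into a maximum matching
        sometimes_matched = any(
            lift.matching_size(skip_out=u, skip_in=i) == mu - 1
            for u in in_arcs.get(i, [])
        )
        classes[v] = "intermittent" if sometimes_matched else "critical"
    return classes


def classify_links(g: nx.DiGraph) -> dict[tuple[str, str], str]:
    """Classify each arc by its role across all maximum matchings."""
    if g.number_of_nodes() == 0:
        raise ValueError("graph must be nonempty")
    lift = _Lift(g)
    cols = lift.matching_columns()
    mu = int((cols >= 0).sum())
    classes: dict[tuple[str, str], str] = {}
    for u, v in lift.arcs:
        arc = (lift.nodes[u], lift.nodes[v])
        if cols[v] == u:
            # in the base maximum matching, hence in some; critical iff its
            # removal lowers the matching number
            critical = lift.matching_size(skip_arc=(u, v)) == mu - 1
            classes[arc] = "critical" if critical else "ordinary"
        else:
            # absent from one maximum matching, so not critical; redundant
            # iff it can enter no maximum matching
            in_some = lift.matching_size(skip_out=u, skip_in=v) == mu - 1
            classes[arc] = "ordinary" if in_some else "redundant"
    return classes


def undirected_link_classes(
    network: TypedNetwork, arc_classes: dict[tuple[str, str], str]
) -> dict[tuple[str, str, str], str]:
    """Collapse antiparallel arc classes back onto the original edges; an
    undirected edge inherits the more critical of its two arc classes."""
    out: dict[tuple[str, str, str], str] = {}
    for edge in network:
        if edge.directed:
            out[edge.key()] = arc_classes[(edge.source, edge.target)]
        else:
            a = arc_classes[(edge.source, edge.target)]
            b = arc_classes[(edge.target, edge.source)]
            best = min(a, b, key=_LINK_CLASS_ORDER.__getitem__)
            out[edge.key()] = best
    return out


def controllable_input_set(g: nx.DiGraph) -> set[str]:
    """Driver nodes plus accessibility completion.

    The unmatched-node drivers remove all dilations, but structural
    controllability also requires every node to be accessible from an input.
    Source strongly connected components that contain a cycle but no driver
    are unreachable, so each contributes one extra input node (its
    lexicographically smallest member). With unit-basis input columns on this
    set, the generic system (A, B) is structurally controllable.
    """
    drivers = driver_analysis(g).representative_set
    cond = nx.condensation(g)
    extra: set[str] = set()
    for scc_id in cond.nodes:
        members = set(cond.nodes[scc_id]["members"])
        if cond.in_degree(scc_id) == 0 and len(members) > 1 \
                and not members & drivers:
            extra.add(min(members))
    return drivers | extra


def critical_nodes_from_links(
    link_class: dict[tuple, str], node_class: dict[str, str]
) -> dict[str, str]:
    """Augment node classes with link-derived criticality.

    Under the antiparallel conversion of undirected layers, interior nodes
    are almost never matching-critical (any incident arc can enter some
    maximum matching), yet critical links do occur and their endpoints pin
    down where control is structurally fragile. Critical links therefore
    reveal critical nodes: endpoints of critical links are promoted to the
    critical class; everything else keeps its matching class.
    """
    out = dict(node_class)
    for key, cls in link_class.items():
        if cls != "critical":
            continue
        for end in key[:2]:
            out[end] = "critical"
    return out


def matching_analysis(network: TypedNetwork) -> ControllabilityResult:
    """Full matching-mode analysis of a typed network's directed view."""
    g = directed_view(network)
    result = driver_analysis(g)
    result.node_class = classify_nodes(g)
    result.link_class = classify_links(g)
    return result


# ---------------------------------------------------------------------------
# exhaustive maximum-matching enumeration (small-instance oracle)


def enumerate_matchings_oracle(
    g: nx.DiGraph, max_lift_edges: int = 25
) -> list[frozenset[tuple[str, str]]]:
    """All maximum matchings of the bipartite lift, as sets of arcs (u, v).

    Backtracking over the arc list; guarded to small instances. The empty
    graph has exactly one (empty) maximum matching.
    """
    arcs = sorted(g.edges)
    if len(arcs) > max_lift_edges:
        raise ValueError(
            f"lift has {len(arcs)} edges; oracle guard is {max_lift_edges}"
        )
    best_size = 0
    found: list[frozenset] = []

    def backtrack(idx: int, used_out: set, used_in: set, chosen: list) -> None:
        nonlocal best_size, found
        remaining = len(arcs) - idx
        if len(chosen) + remaining < best_size:
            return
        if idx == len(arcs):
            if len(chosen) > best_size:
                best_size = len(chosen)
                found = [frozenset(chosen)]
            elif len(chosen) == best_size:
                fs = frozenset(chosen)
                if fs not in found:
                    found.append(fs)
            return
        u, v = arcs[idx]
        if u not in used_out and v not in used_in:
            backtrack(idx + 1, used_out | {u}, used_in | {v}, chosen + [(u, v)])
        backtrack(idx + 1, used_out, used_in, chosen)

    backtrack(0, set(), set(), [])
    return found


def oracle_classes(
    g: nx.DiGraph, max_lift_edges: int = 25
) -> tuple[int, dict[str, str], dict[tuple[str, str], str]]:
    """Ground-truth (N_D, node classes, link classes) from full enumeration."""
    matchings = enumerate_matchings_oracle(g, max_lift_edges)
    mu = len(next(iter(matchings)))
    n = g.number_of_nodes()
    nodes = sorted(g.nodes)
    node_class: dict[str, str] = {}
    if mu == n:
        node_class = {v: "intermittent" for v in nodes}
    else:
        for v in nodes:
            matched_in = [any(arc[1] == v for arc in m) for m in matchings]
            if all(matched_in):
                node_class[v] = "redundant"
            elif not any(matched_in):
                node_class[v] = "critical"
            else:
                node_class[v] = "intermittent"
    link_class: dict[tuple[str, str], str] = {}
    for arc in sorted(g.edges):
        present = [arc in m for m in matchings]
        if all(present):
            link_class[arc] = "critical"
        elif not any(present):
            link_class[arc] = "redundant"
        else:
            link_class[arc] = "ordinary"
    return max(n - mu, 1), node_class, link_class


# ---------------------------------------------------------------------------
# minimum dominating set mode


def _domination_number(
    g: nx.Graph,
    forced: frozenset = frozenset(),
    forbidden: frozenset = frozenset(),
    best_known: Optional[int] = None,
) -> tuple[int, Optional[set[str]]]:
    """Exact branch-and-bound domination number with forced/forbidden nodes.

    Returns (gamma, one optimal set); (inf, None) when infeasible. Branching
    picks an undominated vertex with the fewest allowed dominators and tries
    each, in lexicographic order for determinism.
    """
    nodes = sorted(g.nodes)
    closed = {v: frozenset(g.neighbors(v)) | {v} for v in nodes}
    best_size = best_known if best_known is not None else len(nodes) + 1
    best_set: Optional[set] = None

    def undominated(current: set) -> list:
        dominated = set()
        for v in current:
            dominated |= closed[v]
        return [v for v in nodes if v not in dominated]

    def search(current: set) -> None:
        nonlocal best_size, best_set
        if len(current) >= best_size:
            return
        todo = undominated(current)
        if not todo:
            best_size = len(current)
            best_set = set(current)
            return
        # lower bound: each added node dominates at most Delta+1 new vertices
        max_cover = max(len(closed[v]) for v in nodes if v not in forbidden)
        if len(current) + -(-len(todo) // max_cover) >= best_size:
            return
        pivot = min(todo, key=lambda v: (len(closed[v] - forbidden), v))
        candidates = sorted(closed[pivot] - forbidden)
        if not candidates:
            return  # pivot cannot be dominated under the constraints
        for c in candidates:
            search(current | {c})

    if forced & forbidden:
        return (len(nodes) + 1, None)
    search(set(forced))
    if best_set is None:
        return (len(nodes) + 1, None)
    return best_size, best_set


def mds_analysis(
    network_or_graph, exact_limit: int = MDS_EXACT_LIMIT
) -> ControllabilityResult:
    """Domination-number controllability with the same three node classes.

    critical: in every MDS (gamma grows when the node is forbidden);
    redundant: in no MDS (gamma grows when the node is forced);
    intermittent: otherwise.
    """
    if isinstance(network_or_graph, TypedNetwork):
        g = network_or_graph.to_undirected_nx()
    else:
        g = nx.Graph(network_or_graph)
    if g.number_of_nodes() == 0:
        raise ValueError("graph must be nonempty")
    if g.number_of_nodes() > exact_limit:
        raise ValueError(
            f"{g.number_of_nodes()} nodes exceeds the exact-solver limit "
            f"{exact_limit}; reduce the network or raise exact_limit"
        )
    gamma, rep = _domination_number(g)
    classes: dict[str, str] = {}
    for v in sorted(g.nodes):
        g_forbid, _ = _domination_number(g, forbidden=frozenset({v}))
        if g_forbid > gamma:
            classes[v] = "critical"
            continue
        g_force, _ = _domination_number(g, forced=frozenset({v}))
        classes[v] = "intermittent" if g_force == gamma else "redundant"
    return ControllabilityResult(
        mode="mds", n_d=gamma, representative_set=set(rep), node_class=classes
    )


def mds_oracle(g: nx.Graph) -> tuple[int, dict[str, str]]:
    """Subset-enumeration ground truth for gamma and MDS node classes."""
    nodes = sorted(g.nodes)
    closed = {v: set(g.neighbors(v)) | {v} for v in nodes}
    all_mds: list[set] = []
    for size in range(1, len(nodes) + 1):
        for subset in combinations(nodes, size):
            dominated: set = set()
            for v in subset:
                dominated |= closed[v]
            if len(dominated) == len(nodes):
                all_mds.append(set(subset))
        if all_mds:
            break
    gamma = len(all_mds[0]) if all_mds else 0
    classes = {}
    for v in nodes:
        inside = [v in s for s in all_mds]
        if all(inside):
            classes[v] = "critical"
        elif not any(inside):
            classes[v] = "redundant"
        else:
            classes[v] = "intermittent"
    return gamma, classes


# ---------------------------------------------------------------------------
# Kalman rank verification


@dataclass
class KalmanSystem:
    """Linear system wiring A (A[i, j] = strength of node j on node i) and
    driver selector B whose columns are distinct unit basis vectors."""

    A: sympy.Matrix
    B: sympy.Matrix

    def __post_init__(self) -> None:
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        if self.B.shape[0] != n or self.B.shape[1] > n:
            raise ValueError("B must be N x M with M <= N")
        cols = [tuple(self.B[:, j]) for j in range(self.B.shape[1])]
        for c in cols:
            if sum(c) != 1 or any(x not in (0, 1) for x in c):
                raise ValueError("B columns must be unit basis vectors")
        if len(set(cols)) != len(cols):
            raise ValueError("B columns must be distinct")


def kalman_rank(system: KalmanSystem) -> tuple[int, bool]:
    """Exact-rational rank of C = [B, AB, ..., A^(N-1)B]; full rank N means
    controllable. Capped at N <= 12: entries grow like ||A||^N, so exact
    arithmetic is required for a certificate-grade answer."""
    n = system.A.shape[0]
    if n > KALMAN_EXACT_LIMIT:
        raise ValueError(f"exact Kalman rank limited to N <= {KALMAN_EXACT_LIMIT}")
    blocks = []
    power = system.B
    for _ in range(n):
        blocks.append(power)
        power = system.A @ power
    c = sympy.Matrix.hstack(*blocks)
    rank = c.rank()
    return int(rank), rank == n


def system_from_graph(
    g: nx.DiGraph, drivers: set[str], rng: np.random.Generator
) -> KalmanSystem:
    """Integer-weight realization of a digraph: A[i, j] = random weight in
    1..9 for each arc j -> i; B selects the driver nodes."""
    nodes = sorted(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    a = sympy.zeros(n, n)
    for u, v in sorted(g.edges):
        a[index[v], index[u]] = int(rng.integers(1, 10))
    drv = sorted(drivers)
    b = sympy.zeros(n, len(drv))
    for j, d in enumerate(drv):
        b[index[d], j] = 1
    return KalmanSystem(a, b)
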