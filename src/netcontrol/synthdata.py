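"""Seeded synthetic inputs with the statistical structure the analysis assumes.

The generators emulate the shape of a two-phenotype tumor cell-line study:
a log2-scale expression matrix with planted signed fold-change effects, a
scale-free protein interactome, a bipartite miRNA->gene target layer, an
overlapping protein-complex catalog, and a sparse drug->gene table. All
generators are pure functions of (parameters, seed); each draws from its own
named RNG stream so changing one stage never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .catalog import ComplexCatalog
from .network import Edge, Node, TypedNetwork

# Stream tags keep the per-generator RNGs independent for a shared user seed.
_STREAMS = {
    "expression": 101,
    "interactome": 202,
    "mirna": 303,
    "complexes": 404,
    "drugs": 505,
}


def _rng(stream: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


def _check_finite(**params: float) -> None:
    for name, value in params.items():
        if not math.isfinite(value):
            raise ValueError(f"parameter {name!r} must be finite, got {value!r}")


@dataclass
class SimTruth:
    """Ground truth of a simulated expression experiment."""

    planted_de: list[tuple[str, float]]
    generator_params: dict
    seed: int

    def planted_ids(self) -> set[str]:
        return {gene for gene, _ in self.planted_de}


@dataclass
class ExpressionMatrix:
    """Log2-intensity matrix, genes x samples, with a two-group phenotype map."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match gene/sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        groups = set(self.group_of.values())
        if groups - {"A", "B"}:
            raise ValueError(f"unknown group labels {groups - {'A', 'B'}}")
        for g in ("A", "B"):
            if sum(1 for s in self.sample_ids if self.group_of[s] == g) < 2:
                raise ValueError(f"group {g} needs at least 2 samples")

    def group_columns(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.sample_ids) if self.group_of[s] == group]
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def simulate_expression(
    n_genes: int = 500,
    n_per_group: int = 20,
    de_fraction: float = 0.1,
    effect_log2fc: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Two-group log2 expression with planted signed fold-change effects.

    A ``de_fraction`` share of genes receives a group-A mean shift of
    +/- ``effect_log2fc`` (sign Bernoulli(0.5), recorded in the truth record);
    all other genes have equal group means. Per-cell noise is independent
    Gaussian with sd ``noise_sd`` on the log2 scale.
    """
    _check_finite(de_fraction=de_fraction, effect_log2fc=effect_log2fc, noise_sd=noise_sd)
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must lie in [0, 1]")
    if effect_log2fc <= 0 or noise_sd <= 0:
        raise ValueError("effect_log2fc and noise_sd must be positive")

    rng = _rng("expression", seed)
    if gene_ids is None:
        gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    gene_ids = list(gene_ids)
    sample_ids = [f"A{i:02d}" for i in range(n_per_group)] + [
        f"B{i:02d}" for i in range(n_per_group)
    ]
    group_of = {s: s[0] for s in sample_ids}

    base = rng.normal(8.0, 1.5, size=n_genes)
    values = np.tile(base[:, None], (1, 2 * n_per_group))

    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    planted: list[tuple[str, float]] = []
    for j, sign in zip(de_idx, signs):
        effect = float(sign * effect_log2fc)
        values[j, :n_per_group] += effect  # group A shifted; log2FC = A - B = effect
        planted.append((gene_ids[j], effect))

    values = values + rng.normal(0.0, noise_sd, size=values.shape)

    truth = SimTruth(
        planted_de=sorted(planted),
        generator_params=dict(
            n_genes=n_genes,
            n_per_group=n_per_group,
            de_fraction=de_fraction,
            effect_log2fc=effect_log2fc,
            noise_sd=noise_sd,
        ),
        seed=int(seed),
    )
    return ExpressionMatrix(values, gene_ids, sample_ids, group_of), truth


def simulate_interactome(
    n_nodes: int,
    m_attach: int,
    seed: int = 0,
    node_ids: Sequence[str] | None = None,
) -> TypedNetwork:
    """Scale-free undirected interactome by preferential attachment.

    Most nodes end up weakly connected while a few hubs dominate, the degree
    structure physical interactomes are assumed to have. Node kind is protein.
    """
    if not 1 <= m_attach < n_nodes:
        raise ValueError("require 1 <= m_attach < n_nodes")
    if node_ids is not None and len(node_ids) != n_nodes:
        raise ValueError("node_ids length must equal n_nodes")
    rng = _rng("interactome", seed)
    g = nx.barabasi_albert_graph(n_nodes, m_attach, seed=int(rng.integers(2**31)))
    ids = list(node_ids) if node_ids is not None else [f"P{i:04d}" for i in range(n_nodes)]
    net = TypedNetwork()
    for nid in ids:
        net.add_node(Node(nid, "protein"))
    for u, v in sorted(g.edges()):
        net.add_edge(Edge(ids[u], ids[v], "ppi", directed=False))
    return net


def simulate_mirna_targets(
    gene_ids: Sequence[str],
    n_mirnas: int,
    targets_per_mirna: int,
    seed: int = 0,
) -> TypedNetwork:
    """Bipartite miRNA->gene target layer; each miRNA hits ``targets_per_mirna``
    distinct genes sampled without replacement."""
    if len(gene_ids) == 0:
        raise ValueError("gene_ids must be nonempty")
    if targets_per_mirna > len(gene_ids):
        raise ValueError("targets_per_mirna cannot exceed the gene pool")
    rng = _rng("mirna", seed)
    gene_ids = list(gene_ids)
    net = TypedNetwork()
    for gid in gene_ids:
        net.add_node(Node(gid, "gene"))
    for m in range(n_mirnas):
        mid = f"miR-{m:03d}"
        net.add_node(Node(mid, "mirna"))
        targets = rng.choice(len(gene_ids), size=targets_per_mirna, replace=False)
        for t in sorted(targets):
            net.add_edge(Edge(mid, gene_ids[t], "mirna_target", directed=True))
    return net


def simulate_complexes_and_drugs(
    protein_ids: Sequence[str],
    n_complexes: int,
    size_range: tuple[int, int] = (3, 6),
    n_drugs: int = 0,
    edges_per_drug: int = 2,
    seed: int = 0,
) -> tuple[ComplexCatalog, TypedNetwork]:
    """Overlapping protein complexes plus a sparse drug->gene layer."""
    lo, hi = size_range
    if lo > hi:
        raise ValueError("size_range min must not exceed max")
    if lo < 2:
        raise ValueError("size_range min must be >= 2")
    if hi > len(protein_ids):
        raise ValueError("size_range max cannot exceed the protein pool")
    protein_ids = list(protein_ids)

    crng = _rng("complexes", seed)
    complexes: dict[str, set[str]] = {}
    for c in range(n_complexes):
        size = int(crng.integers(lo, hi + 1))
        members = crng.choice(len(protein_ids), size=size, replace=False)
        complexes[f"CPX-{c:03d}"] = {protein_ids[i] for i in members}
    catalog = ComplexCatalog(complexes)

    drng = _rng("drugs", seed)
    layer = TypedNetwork()
    if edges_per_drug > len(protein_ids):
        raise ValueError("edges_per_drug cannot exceed the protein pool")
    for d in range(n_drugs):
        did = f"DRUG-{d:03d}"
        layer.add_node(Node(did, "drug"))
        targets = drng.choice(len(protein_ids), size=edges_per_drug, replace=False)
        for t in sorted(targets):
            gid = protein_ids[t]
            if gid not in layer.nodes:
                layer.add_node(Node(gid, "gene"))
            layer.add_edge(Edge(did, gid, "drug_gene", directed=True))
    return catalog, layer
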