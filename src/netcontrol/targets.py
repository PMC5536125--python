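"""Composite-target extraction against a protein-complex catalog.

Critical nodes identified by the controllability analysis are mapped onto
protein complexes; each complex with critical members inside the network
becomes a candidate *composite target* — a set of interacting proteins whose
joint perturbation may control the system better than any single node. Each
candidate carries an eigenvector localization score (the mass of a chosen
unit eigenvector on its members) and the list is ranked deterministically.
A drug->gene overlay turns ranked complexes into actionable drug rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .catalog import ComplexCatalog
from .network import TypedNetwork
from .spectral import SpectralResult, lowest_nonzero_eigen


@dataclass
class CompositeTarget:
    complex_name: str
    members_in_network: set[str]
    critical_members: set[str]
    induced_edges: int
    connected: bool                 # critical members in one induced component
    localization_score: float       # eigenvector mass on members_in_network
    rank: int = 0


def fraction_in_complex(
    node_class: dict[str, str], catalog: ComplexCatalog
) -> float | None:
    """Percentage of critical nodes annotated to at least one complex.

    Returns None (with no silent zero) when there are no critical nodes —
    the statistic is undefined, not zero.
    """
    critical = [v for v, c in node_class.items() if c == "critical"]
    if not critical:
        return None
    members = catalog.membership()
    hit = sum(1 for v in critical if v in members)
    return 100.0 * hit / len(critical)


def extract_composite_targets(
    network: TypedNetwork,
    node_class: dict[str, str],
    catalog: ComplexCatalog,
    spectrum: SpectralResult,
    eigen_choice: str = "principal",
    min_induced_edges: int = 1,
) -> tuple[list[CompositeTarget], list[str]]:
    """Rank complexes by critical-member count then eigenvector localization.

    A complex qualifies when >= 2 of its members are in the network and >= 1
    is critical; complexes whose members induce fewer than
    ``min_induced_edges`` edges are discarded ("composite" means interacting)
    and returned in the discard log.
    """
    if sorted(spectrum.node_ids) != sorted(network.nodes):
        raise ValueError("spectrum was not computed on this network's node set")
    if eigen_choice == "principal":
        _, vector = spectrum.principal()
    elif eigen_choice == "lowest_nonzero":
        _, vector, _ = lowest_nonzero_eigen(spectrum)
    else:
        raise ValueError(f"unknown eigen_choice {eigen_choice!r}")
    mass = dict(zip(spectrum.node_ids, (vector**2).astype(float)))

    g = network.to_undirected_nx()
    candidates: list[CompositeTarget] = []
    discarded: list[str] = []
    for name in sorted(catalog.complexes):
        members = catalog.complexes[name] & set(network.nodes)
        critical = {v for v in members if node_class.get(v) == "critical"}
        if len(members) < 2 or not critical:
            continue
        induced = g.subgraph(members)
        if induced.number_of_edges() < min_induced_edges:
            discarded.append(name)
            continue
        components = list(nx.connected_components(induced))
        connected = any(critical <= comp for comp in components)
        score = float(sum(mass[v] for v in members))
        candidates.append(
            CompositeTarget(
                complex_name=name,
                members_in_network=members,
                critical_members=critical,
                induced_edges=induced.number_of_edges(),
                connected=connected,
                localization_score=score,
            )
        )
    candidates.sort(
        key=lambda t: (-len(t.critical_members), -t.localization_score, t.complex_name)
    )
    for i, t in enumerate(candidates, start=1):
        t.rank = i
    return candidates, discarded


def overlay_drugs(
    targets: list[CompositeTarget], drug_layer: TypedNetwork
) -> pd.DataFrame:
    """Inner join of drug->gene arcs with composite-target membership.

    One row per (drug, gene, complex) triple, sorted deterministically.
    """
    for edge in drug_layer:
        if edge.layer != "drug_gene":
            raise ValueError("drug layer must contain only drug_gene edges")
    rows = []
    for edge in drug_layer:
        for t in targets:
            if edge.target in t.members_in_network:
                rows.append(
                    dict(
                        drug=edge.source,
                        gene=edge.target,
                        complex_name=t.complex_name,
                        gene_is_critical=edge.target in t.critical_members,
                    )
                )
    frame = pd.DataFrame(rows, columns=["drug", "gene", "complex_name",
                                        "gene_is_critical"])
    return frame.sort_values(["drug", "gene", "complex_name"]).reset_index(drop=True)


def targets_to_frame(targets: list[CompositeTarget]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                rank=t.rank,
                complex_name=t.complex_name,
                n_members_in_network=len(t.members_in_network),
                n_critical=len(t.critical_members),
                critical_members=";".join(sorted(t.critical_members)),
                induced_edges=t.induced_edges,
                connected=t.connected,
                localization_score=t.localization_score,
            )
            for t in targets
        ]
    )
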