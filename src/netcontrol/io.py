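"""Readers and writers for the package's plain-text formats.

Expression matrices and sample annotations travel as TSV; networks as typed
edge-list TSV (source, target, layer, directed, weight) or SIF (source,
interaction, target); complex catalogs as GMT. All readers validate the
container invariants and report offending line numbers.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import ComplexCatalog
from .network import DIRECTED_LAYERS, Edge, LAYERS, Node, TypedNetwork
from .synthdata import ExpressionMatrix, SimTruth

_KIND_OF_LAYER_SOURCE = {
    "coexpression": "gene",
    "ppi": "protein",
    "mirna_target": "mirna",
    "drug_gene": "drug",
}
_KIND_OF_LAYER_TARGET = {
    "coexpression": "gene",
    "ppi": "protein",
    "mirna_target": "gene",
    "drug_gene": "gene",
}


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# expression


def write_expression(expr: ExpressionMatrix, matrix_path, annotation_path) -> None:
    expr.to_frame().to_csv(matrix_path, sep="\t", index_label="gene")
    with open(annotation_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample", "group"])
        for s in expr.sample_ids:
            w.writerow([s, expr.group_of[s]])


def read_expression(matrix_path, annotation_path) -> ExpressionMatrix:
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
    ann = pd.read_csv(annotation_path, sep="\t")
    group_of = dict(zip(ann["sample"].astype(str), ann["group"].astype(str)))
    return ExpressionMatrix(
        values=frame.to_numpy(dtype=float),
        gene_ids=[str(g) for g in frame.index],
        sample_ids=[str(s) for s in frame.columns],
        group_of=group_of,
    )


def write_truth(truth: SimTruth, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "effect_log2fc"])
        for gene, effect in truth.planted_de:
            w.writerow([gene, repr(effect)])


# ---------------------------------------------------------------------------
# networks


def write_network_tsv(net: TypedNetwork, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["source", "target", "layer", "directed", "weight"])
        for edge in sorted(net, key=lambda e: e.key()):
            w.writerow(
                [
                    edge.source,
                    edge.target,
                    edge.layer,
                    "true" if edge.directed else "false",
                    "" if edge.weight is None else repr(edge.weight),
                ]
            )


def write_node_table(net: TypedNetwork, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "kind", "de_status", "mutated"])
        for nid in net.node_ids():
            n = net.nodes[nid]
            w.writerow([n.id, n.kind, n.de_status, "true" if n.mutated else "false"])


def read_network_tsv(path, node_table=None) -> TypedNetwork:
    """Typed edge list; node kinds inferred from layer roles unless a node
    table is supplied. Self-loops and duplicate (source, target, layer) rows
    are rejected with their line number."""
    net = TypedNetwork()
    if node_table is not None:
        nodes = pd.read_csv(node_table, sep="\t")
        for _, row in nodes.iterrows():
            net.add_node(
                Node(
                    str(row["id"]),
                    str(row["kind"]),
                    de_status=str(row.get("de_status", "none")),
                    mutated=str(row.get("mutated", "false")).lower() == "true",
                )
            )
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[:4] != ["source", "target", "layer", "directed"]:
            raise FormatError(f"{path}: line 1: bad header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c for c in row):
                continue
            if len(row) < 4:
                raise FormatError(f"{path}: line {lineno}: expected >= 4 columns")
            source, target, layer, directed_s = row[:4]
            if layer not in LAYERS:
                raise FormatError(f"{path}: line {lineno}: unknown layer {layer!r}")
            if source == target:
                raise FormatError(f"{path}: line {lineno}: self-loop on {source!r}")
            directed = directed_s.strip().lower() == "true"
            weight = None
            if len(row) >= 5 and row[4] != "":
                weight = float(row[4])
            for end, kind_map in ((source, _KIND_OF_LAYER_SOURCE),
                                  (target, _KIND_OF_LAYER_TARGET)):
                if end not in net.nodes:
                    if node_table is not None:
                        raise FormatError(
                            f"{path}: line {lineno}: endpoint {end!r} "
                            "missing from node table"
                        )
                    net.add_node(Node(end, kind_map[layer]))
            try:
                net.add_edge(Edge(source, target, layer, directed, weight))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return net


def write_sif(net: TypedNetwork, path) -> None:
    with open(path, "w", newline="") as fh:
        for edge in sorted(net, key=lambda e: e.key()):
            fh.write(f"{edge.source}\t{edge.layer}\t{edge.target}\n")


def read_sif(path) -> TypedNetwork:
    """SIF rows source <tab> interaction <tab> target(s); the interaction tag
    must be one of the four layer names, which fixes edge direction."""
    net = TypedNetwork()
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 columns")
            source, layer = parts[0], parts[1]
            if layer not in LAYERS:
                raise FormatError(f"{path}: line {lineno}: unknown layer {layer!r}")
            for target in parts[2:]:
                if source == target:
                    raise FormatError(f"{path}: line {lineno}: self-loop on {source!r}")
                for end, kind_map in ((source, _KIND_OF_LAYER_SOURCE),
                                      (target, _KIND_OF_LAYER_TARGET)):
                    if end not in net.nodes:
                        net.add_node(Node(end, kind_map[layer]))
                try:
                    net.add_edge(
                        Edge(source, target, layer, layer in DIRECTED_LAYERS)
                    )
                except ValueError as exc:
                    raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return net


# ---------------------------------------------------------------------------
# GMT catalogs


def write_gmt(catalog: ComplexCatalog, path) -> None:
    with open(path, "w", newline="") as fh:
        for name in sorted(catalog.complexes):
            members = "\t".join(sorted(catalog.complexes[name]))
            fh.write(f"{name}\t{catalog.source}\t{members}\n")


def read_gmt(path) -> ComplexCatalog:
    complexes: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 fields "
                                  "(name, description, members...)")
            name = fields[0]
            if name in complexes:
                raise FormatError(f"{path}: line {lineno}: duplicate complex "
                                  f"name {name!r}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise FormatError(f"{path}: line {lineno}: complex {name!r} "
                                  "has no members")
            complexes[name] = members
    return ComplexCatalog(complexes, source=str(path))
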