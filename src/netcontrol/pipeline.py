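"""End-to-end pipeline: simulation (or file inputs) through composite targets.

Stage order mirrors the analysis flow: simulate -> differential expression ->
co-expression network -> multilayer assembly -> controllability -> spectral
localization -> composite targets -> drug overlay. A single JSON report
collects per-stage summaries; identical (config, seed) pairs produce
byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import controllability as ctrl
from . import coexpression as coex
from . import diffexpr, io, multinet, spectral, synthdata, targets as targets_mod

logger = logging.getLogger("netcontrol.pipeline")

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Stage parameters. The fold-change (1.5) and co-expression edge-weight
    (0.05) defaults are the analysis constants; every stage reads them from
    here rather than hard-coding them."""

    seed: int = 0
    out_dir: str = "netcontrol_out"
    # simulate
    simulate: bool = True
    n_genes: int = 500
    n_per_group: int = 20
    de_fraction: float = 0.1
    effect_log2fc: float = 2.0
    noise_sd: float = 0.5
    interactome_m_attach: int = 2
    n_mirnas: int = 20
    targets_per_mirna: int = 10
    n_complexes: int = 30
    complex_size_range: tuple[int, int] = (3, 6)
    n_drugs: int = 10
    edges_per_drug: int = 3
    # file inputs (used when simulate is False)
    expression_path: str | None = None
    annotation_path: str | None = None
    interactome_path: str | None = None
    mirna_path: str | None = None
    gmt_path: str | None = None
    drug_path: str | None = None
    # diffexpr
    fc_cutoff: float = diffexpr.DEFAULT_FC_CUTOFF
    q_cutoff: float | None = None
    adjust_method: str = "fdr_bh"
    # coexpression
    weight_cutoff: float = coex.DEFAULT_WEIGHT_CUTOFF
    beta: int | None = None
    beta_grid: list[int] = field(default_factory=lambda: list(range(1, 21)))
    r2_target: float = 0.8
    # controllability / spectral / targets
    controllability_mode: str = "matching"
    link_critical_nodes: bool = True   # promote critical-link endpoints for targets
    mds_exact_limit: int = ctrl.MDS_EXACT_LIMIT
    matrix_kind: str = "adjacency"
    ipr_convention: str = "l2"
    eigen_choice: str = "principal"
    localization_threshold: float = 10.0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_inputs(config: PipelineConfig):
    """Either simulate every input from the seed or read the supplied files."""
    if config.simulate:
        expr, truth = synthdata.simulate_expression(
            n_genes=config.n_genes,
            n_per_group=config.n_per_group,
            de_fraction=config.de_fraction,
            effect_log2fc=config.effect_log2fc,
            noise_sd=config.noise_sd,
            seed=config.seed,
        )
        interactome = synthdata.simulate_interactome(
            config.n_genes,
            config.interactome_m_attach,
            seed=config.seed,
            node_ids=expr.gene_ids,
        )
        mirna = synthdata.simulate_mirna_targets(
            expr.gene_ids, config.n_mirnas, config.targets_per_mirna,
            seed=config.seed,
        )
        catalog, drugs = synthdata.simulate_complexes_and_drugs(
            expr.gene_ids,
            config.n_complexes,
            config.complex_size_range,
            config.n_drugs,
            config.edges_per_drug,
            seed=config.seed,
        )
        return expr, truth, interactome, mirna, catalog, drugs
    missing = [
        name
        for name, path in (
            ("expression_path", config.expression_path),
            ("annotation_path", config.annotation_path),
            ("interactome_path", config.interactome_path),
            ("mirna_path", config.mirna_path),
            ("gmt_path", config.gmt_path),
            ("drug_path", config.drug_path),
        )
        if path is None
    ]
    if missing:
        raise ValueError(f"simulate=False but inputs missing: {', '.join(missing)}")
    expr = io.read_expression(config.expression_path, config.annotation_path)
    interactome = io.read_network_tsv(config.interactome_path)
    mirna = io.read_network_tsv(config.mirna_path)
    catalog = io.read_gmt(config.gmt_path)
    drugs = io.read_network_tsv(config.drug_path)
    return expr, None, interactome, mirna, catalog, drugs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, write stage outputs under ``config.out_dir``, and
    return the JSON-serializable report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    logger.info("seed=%s config_hash=%s", config.seed, config.config_hash())

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }

    # 1. inputs -------------------------------------------------------------
    expr, truth, interactome, mirna, catalog, drugs = _load_inputs(config)
    if truth is not None:
        io.write_expression(expr, out / "expression.tsv", out / "samples.tsv")
        io.write_truth(truth, out / "truth.tsv")
    report["stages"]["simulate"] = {
        "simulated": config.simulate,
        "n_genes": len(expr.gene_ids),
        "n_samples": len(expr.sample_ids),
        "n_planted_de": len(truth.planted_de) if truth is not None else None,
        "interactome_edges": interactome.n_edges(),
        "mirna_edges": mirna.n_edges(),
        "n_complexes": len(catalog),
        "drug_edges": drugs.n_edges(),
    }
    logger.info("inputs ready (%.2fs)", time.perf_counter() - t0)

    # 2. differential expression -------------------------------------------
    records = diffexpr.build_records(expr, method=config.adjust_method)
    records = diffexpr.select_degs(records, config.fc_cutoff, config.q_cutoff)
    deg_ids = diffexpr.selected_ids(records)
    direction_of = {r.gene: r.direction for r in records if r.selected}
    diffexpr.records_to_frame(records).to_csv(out / "degs.tsv", sep="\t", index=False)
    report["stages"]["diffexpr"] = {
        "n_selected": len(deg_ids),
        "n_up": sum(1 for r in records if r.direction == "up"),
        "n_down": sum(1 for r in records if r.direction == "down"),
        "fc_cutoff": config.fc_cutoff,
    }
    if len(deg_ids) < 3:
        raise RuntimeError(
            f"only {len(deg_ids)} genes pass |log2FC| >= {config.fc_cutoff}; "
            "not enough to build networks"
        )

    # 3. co-expression network ---------------------------------------------
    sub_idx = [expr.gene_ids.index(g) for g in deg_ids]
    sub_expr = synthdata.ExpressionMatrix(
        expr.values[sub_idx, :], deg_ids, expr.sample_ids, expr.group_of
    )
    coex_config = coex.CoexpressionConfig(
        beta=config.beta,
        beta_grid=list(config.beta_grid),
        r2_target=config.r2_target,
        weight_cutoff=config.weight_cutoff,
    )
    coex_net, coex_info = coex.build_coexpression_network(sub_expr, coex_config)
    io.write_network_tsv(coex_net, out / "coexpression.tsv")
    report["stages"]["coexpression"] = {
        "n_nodes": coex_net.n_nodes(),
        "n_edges": coex_net.n_edges(),
        **coex_info,
    }

    # 4. multilayer assembly -------------------------------------------------
    ppi_net = multinet.expand_first_order(deg_ids, interactome)
    deg_set = set(deg_ids)
    active_mirnas = {e.source for e in mirna if e.target in deg_set}
    mirna_sub = mirna.subgraph(active_mirnas | deg_set)
    merged = multinet.merge_layers([coex_net, ppi_net, mirna_sub])
    merged = multinet.annotate_de(merged, direction_of)
    io.write_network_tsv(merged, out / "multilayer.tsv")
    io.write_node_table(merged, out / "nodes.tsv")
    cent = multinet.centralities(merged)
    cent.to_csv(out / "centralities.tsv", sep="\t")
    report["stages"]["multinet"] = {
        "n_nodes": merged.n_nodes(),
        "n_edges": merged.n_edges(),
        "layers": sorted(merged.layers_present()),
        "max_degree": int(cent["degree"].max()),
    }

    # 5. controllability ------------------------------------------------------
    if config.controllability_mode == "matching":
        result = ctrl.matching_analysis(merged)
        link_classes = ctrl.undirected_link_classes(merged, result.link_class)
        link_counts: dict[str, int] = {"critical": 0, "ordinary": 0, "redundant": 0}
        for c in link_classes.values():
            link_counts[c] += 1
        if config.link_critical_nodes:
            target_classes = ctrl.critical_nodes_from_links(
                link_classes, result.node_class
            )
        else:
            target_classes = result.node_class
    elif config.controllability_mode == "mds":
        result = ctrl.mds_analysis(merged, exact_limit=config.mds_exact_limit)
        link_counts = {}
        target_classes = result.node_class
    else:
        raise ValueError(f"unknown controllability mode "
                         f"{config.controllability_mode!r}")
    with open(out / "node_classes.tsv", "w") as fh:
        fh.write("id\tclass\tis_driver_in_representative\n")
        for nid in sorted(result.node_class):
            drv = "true" if nid in result.representative_set else "false"
            fh.write(f"{nid}\t{result.node_class[nid]}\t{drv}\n")
    n_link_critical_nodes = sum(
        1
        for nid, c in target_classes.items()
        if c == "critical" and result.node_class.get(nid) != "critical"
    )
    report["stages"]["controllability"] = {
        "mode": result.mode,
        "n_d": result.n_d,
        "node_class_counts": result.class_counts(),
        "link_class_counts": link_counts,
        "n_link_critical_nodes": n_link_critical_nodes,
    }

    # 6. spectral --------------------------------------------------------------
    spec = spectral.eigendecompose(
        merged, matrix_kind=config.matrix_kind, convention=config.ipr_convention
    )
    table = spectral.spectrum_table(spec, config.localization_threshold)
    table.to_csv(out / "spectrum.tsv", sep="\t", index=False)
    principal_ipr = spec.ipr(0)
    try:
        low_lambda, _, low_ipr = spectral.lowest_nonzero_eigen(spec)
    except ValueError:
        low_lambda, low_ipr = None, None
    report["stages"]["spectral"] = {
        "matrix_kind": spec.matrix_kind,
        "n": spec.n,
        "lambda_max": float(spec.eigenvalues[0]),
        "principal_ipr": principal_ipr,
        "lowest_nonzero_eigenvalue": low_lambda,
        "lowest_nonzero_ipr": low_ipr,
        "n_localized": int((table["localization"] == "localized").sum())
        if config.ipr_convention == "l2"
        else None,
    }

    # 7. composite targets ----------------------------------------------------
    fraction = targets_mod.fraction_in_complex(target_classes, catalog)
    composite, discarded = targets_mod.extract_composite_targets(
        merged, target_classes, catalog, spec, eigen_choice=config.eigen_choice
    )
    targets_mod.targets_to_frame(composite).to_csv(
        out / "composite_targets.tsv", sep="\t", index=False
    )
    report["stages"]["targets"] = {
        "fraction_critical_in_complex_pct": fraction,
        "n_composite_targets": len(composite),
        "n_discarded_no_edges": len(discarded),
        "top_targets": [
            {
                "rank": t.rank,
                "complex": t.complex_name,
                "n_critical": len(t.critical_members),
                "localization_score": t.localization_score,
            }
            for t in composite[:5]
        ],
    }

    # 8. drug overlay ----------------------------------------------------------
    overlay = targets_mod.overlay_drugs(composite, drugs)
    overlay.to_csv(out / "drug_overlay.tsv", sep="\t", index=False)
    report["stages"]["drugs"] = {
        "n_rows": int(len(overlay)),
        "n_drugs_hitting_targets": int(overlay["drug"].nunique())
        if len(overlay)
        else 0,
        "n_critical_gene_rows": int(overlay["gene_is_critical"].sum())
        if len(overlay)
        else 0,
    }

    logger.info("pipeline done in %.2fs", time.perf_counter() - t0)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return report
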