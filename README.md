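# netcontrol

Controllability-guided composite-target discovery in multilayer molecular
networks.

Tumor cell-line panels profiled under contrasting phenotypes (for example
invasive vs non-invasive, or tumorigenic vs non-tumorigenic osteosarcoma
lines) raise a systems-level question: which genes, or which *sets* of
interacting proteins, would an intervention have to hit to steer the
regulatory network from one state toward another? `netcontrol` answers this
with structural control theory. It is written for computational biologists
who have a two-group expression contrast, a reference interactome, a
miRNA–target table, a protein-complex catalog, and a drug–gene table, and
who want a reproducible path from differential expression to a ranked list
of actionable composite targets.

## The analysis

1. **Differential expression.** Per gene, log₂FC = mean log₂ intensity in
   group A − group B, a Welch two-sample *t* test, and Benjamini–Hochberg
   FDR. Selection uses the fold-change rule |log₂FC| ≥ 1.5 (inclusive);
   an FDR threshold is optional.
2. **Co-expression network.** Soft-threshold adjacency
   *a\_ij* = |cor(*g\_i*, *g\_j*)|^β with β chosen as the smallest power whose
   weighted-degree distribution reaches a scale-free fit R² ≥ 0.8, then
   topological overlap
   TOM*\_ij* = (Σ*\_u a\_iu a\_uj* + *a\_ij*) / (min(*k\_i*, *k\_j*) + 1 − *a\_ij*),
   keeping pairs with TOM ≥ 0.05.
3. **Multilayer assembly.** First-order interactome expansion around the
   selected genes (induced subgraph over seeds plus direct neighbors),
   merged with the co-expression layer and the miRNA→target layer; degree,
   betweenness, clustering and maximal-clique centrality profile the hubs.
4. **Structural controllability.** For the directed view (undirected edges
   become antiparallel arc pairs), a maximum matching of the bipartite lift
   gives the minimum driver count N_D = max(N − μ, 1). Nodes are classified
   critical / intermittent / redundant according to whether they are a
   driver in every / some / no minimum driver configuration, links by their
   role across all maximum matchings; a minimum-dominating-set mode (exact
   branch and bound) offers the domination-based reading, and a
   Kalman-rank verifier (exact rational arithmetic on
   C = [B, AB, …, A^(N−1)B]) certifies controllability on small systems.
5. **Spectral localization.** Eigen-decomposition of the adjacency (or
   Laplacian); per eigenvector the inverse participation ratio
   IPR = Σᵢ eᵢ⁴ of the unit-normalized vector measures localization
   (1 = all mass on one node, 1/n = uniform), PR = 1/IPR.
6. **Composite targets.** Protein complexes intersected with the network:
   every complex with ≥ 2 members present and ≥ 1 critical member becomes a
   candidate, scored by the eigenvector mass on its members and ranked;
   drug→gene interactions are joined onto the ranked complexes.

A seeded synthetic-data module generates a two-group expression matrix with
planted signed log₂ effects, a preferential-attachment interactome, a
bipartite miRNA→gene layer, an overlapping complex catalog, and a sparse
drug–gene table, so the full analysis runs and is tested entirely offline.

## Worked example

```bash
netcontrol run --seed 1 --out run_demo
```

runs every stage on synthetic inputs (500 genes, 20 samples per group, 10%
planted effects of ±2.0 log₂ units, noise sd 0.5) and prints:

```
{"controllability": {"link_class_counts": {"critical": 38, "ordinary": 848,
  "redundant": 630}, "mode": "matching", "n_d": 28,
  "n_link_critical_nodes": 76, "node_class_counts": {"critical": 16,
  "intermittent": 37, "redundant": 124}},
 "diffexpr": {"fc_cutoff": 1.5, "n_down": 25, "n_selected": 50, "n_up": 25},
 "targets": {"fraction_critical_in_complex_pct": 16.304347826086957,
  "n_composite_targets": 1, "n_discarded_no_edges": 6,
  "top_targets": [{"complex": "CPX-013",
  "localization_score": 0.0397189540228326, "n_critical": 3, "rank": 1}]}}
```

Reading the numbers: all 50 planted genes survive the |log₂FC| ≥ 1.5 rule
(25 up, 25 down). The merged 177-node multilayer network needs 28 driver
nodes; the 16 matching-critical nodes are the miRNA regulators (pure
sources are drivers in every minimum configuration), while 38 critical
links mark 76 additional structurally fragile gene/protein nodes. Of those
critical nodes, 16.3% sit in at least one cataloged complex, and one
complex qualifies as a composite target: three of its members are critical
and mutually connected, carrying ~4% of the principal eigenvector's mass.
Full per-stage tables (DEGs, edge lists, node classes, spectrum, ranked
targets, drug overlay) and `report.json` land in `run_demo/`. Re-running
with the same seed reproduces the report byte for byte.

The same stages are available as library functions
(`netcontrol.diffexpr`, `.coexpression`, `.multinet`, `.controllability`,
`.spectral`, `.targets`) and as per-stage subcommands
(`simulate`, `deg`, `coexpr`, `net`, `control`, `spectral`, `targets`).

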