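# Methods

## Model and scope

`netcontrol` treats a molecular network as a linear time-invariant system
dx/dt = Ax + Bu, where A (N × N) holds the interaction strengths between
the N molecular species and B (N × M) selects the M nodes that receive an
external input. The system is controllable when the Kalman matrix
C = [B, AB, …, A^(N−1)B] has rank N. Because A is never known numerically
for a cell, the package works structurally: what matters is the wiring
pattern, and results hold for almost every choice of nonzero weights.

The pipeline around this core mirrors a phenotype-contrast study design:
two groups of samples (e.g. invasive vs non-invasive cell lines) are
contrasted per gene, the differential genes seed network construction in
three layers (co-expression, physical protein interactions, miRNA→target
regulation), the merged multilayer network is analyzed for driver nodes and
critical elements, eigenvector localization points at structurally dominant
sub-networks, and protein complexes enriched in critical members are ranked
as composite intervention targets with a drug–gene overlay.

## Differential expression

Log₂-scale intensities are assumed (the fold change of raw intensities is a
difference of log-intensities). Per gene: Welch's unequal-variance t test
and Benjamini–Hochberg adjustment across genes (Bonferroni available).
Selection applies |log₂FC| ≥ `fc_cutoff` (default 1.5, boundary inclusive);
`q_cutoff` is `None` by default because the fold-change rule alone defines
selection — FDR values are reported alongside. A deliberate simplification:
no empirical-Bayes variance moderation is applied; at the sample sizes the
package targets (≥ 10 per group) the moderated and plain Welch tests rank
genes nearly identically, and the selection rule is fold-change-driven
anyway. Degenerate genes (zero variance in both groups) get p = 1 when the
group means are equal and p = 0 otherwise, so pipelines never abort on flat
synthetic genes.

## Co-expression network

Unsigned soft-threshold adjacency a_ij = |cor|^β. β is the smallest power
in `beta_grid` (default 1..20) whose weighted-degree distribution reaches a
scale-free fit of R² ≥ `r2_target` (default 0.8); if none does, the argmax
is used and flagged. The fit bins positive connectivities into 10
equal-occupancy bins (duplicate quantile edges collapsed) and regresses
log₁₀ of the frequency *density* (bin count / (n · bin width)) on log₁₀ of
the mean bin connectivity; the density form is required because
equal-occupancy bins have constant raw frequency by construction. The
topological overlap matrix uses the standard unsigned formula
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), TOM_ii = 1.
Edges are kept when TOM ≥ `weight_cutoff` (default 0.05, applied to TOM
values, not raw correlations). Signed networks and module detection are out
of scope.

## Multilayer assembly

Node identity is global: a gene and its protein product share one id (the
gene/protein kind pair merges; any other kind clash is an id collision).
First-order expansion takes the induced subgraph over seeds plus their
direct neighbors — neighbor–neighbor edges are retained deliberately, since
composite-target extraction later depends on sub-complex connectivity.
Merging unions nodes and layer-keyed edges, so one node pair can carry a
co-expression and a ppi edge simultaneously; differential-expression status
up/down outranks none and mutation flags are OR-ed. Centralities (degree,
unnormalized shortest-path betweenness, local clustering, maximal-clique
centrality MCC(v) = Σ_{cliques C ∋ v} (|C|−1)!) are computed on the simple
unweighted undirected view.

## Structural controllability

Undirected edges become antiparallel arc pairs; miRNA→gene and drug→gene
arcs keep their direction. The bipartite lift places one out-copy and one
in-copy per node and one lift edge per arc; a maximum matching (size μ,
Hopcroft–Karp on a sparse matrix, deterministic under lexicographic node
order) gives N_D = max(N − μ, 1). Node classes over the family of all
maximum matchings: *critical* = in-copy matched in no maximum matching
(always a driver), *redundant* = matched in every one (never a driver),
*intermittent* otherwise. Membership tests use single-element deletions:
v is redundant iff μ(lift − v_in) = μ − 1; an unmatched v is non-critical
iff some in-arc (u→v) satisfies μ(lift − u_out − v_in) = μ − 1. Links:
*critical* iff deletion lowers μ, *redundant* iff the arc can enter no
maximum matching, *ordinary* otherwise; an undirected edge inherits the
more critical of its two arc classes. When the matching is perfect every
node is intermittent and N_D = 1 (one input is always required).

Two consequences of the antiparallel convention are documented rather than
hidden. First, in connected bidirected layers almost every node's in-copy
is matchable, so matching-critical nodes are essentially the pure sources
(miRNAs, isolated genes). Critical links, however, do occur inside
undirected layers, and their endpoints mark where control is structurally
fragile; the pipeline therefore promotes endpoints of critical links to the
critical class for the complex-mapping stage (`link_critical_nodes`
toggle, on by default). Second, the representative driver set removes
dilations but does not guarantee accessibility: source strongly connected
components containing a cycle but no driver are unreachable, so
`controllable_input_set` adds one input per such component. With that
completion, random integer weights on the arcs yield a full-rank Kalman
matrix in ≳ 99% of draws.

The minimum-dominating-set mode answers the same three-way classification
over the family of all MDSs (γ via exact branch and bound; v critical iff
forbidding v raises γ, redundant iff forcing v raises γ). Exact mode is
capped at 40 nodes by default — domination is NP-hard and the
branch-and-bound's pruning is calibrated for desk-scale networks — and the
cap is a hard error, not a silent approximation. Matching mode is the
default throughout.

Kalman rank is computed in exact rational arithmetic (sympy) and capped at
N ≤ 12: entries of C grow like ‖A‖^N and floating-point rank decisions
become untrustworthy well before the cap.

## Spectral localization

Full symmetric eigendecomposition of the adjacency (default) or
combinatorial Laplacian D − A of the simple undirected view; eigenvalues
sorted descending, eigenvectors L2-normalized with the largest-magnitude
component forced positive so outputs are stable across runs. IPR = Σ e⁴ on
the unit vector (∈ [1/n, 1]); PR = 1/IPR. An eigenvector is called
localized when IPR·n ≥ 10 (mass on roughly ≤ n/10 nodes; threshold
configurable). A second convention that first divides components by the
largest-magnitude one is shipped because published IPR values above 1
cannot arise under the unit-L2 formula; it is never the default. Within
degenerate eigenvalue clusters the per-vector IPR is basis-dependent and
flagged as such. The "lowest non-zero eigenvalue" accessor returns the
smallest-magnitude eigenvalue above 1e-9; on the Laplacian its eigenvector
localizes on weakly attached communities.

## Composite targets

A complex qualifies when ≥ 2 members are in the network, ≥ 1 member is
critical, and the members induce at least `min_induced_edges` edges
(default 1 — "composite" means interacting; edgeless complexes go to a
discard log). The localization score is the mass Σ e² of the chosen unit
eigenvector (principal by default; lowest non-zero as the community-probing
alternative) over the members present; scores over a partition of the node
set sum to 1. Ranking is (number of critical members desc, localization
score desc, name asc) — total and deterministic. The
fraction-in-complex statistic is 100 · |critical nodes in ≥ 1 complex| /
|critical nodes|, undefined (explicit `None`) when there are no critical
nodes. No enrichment p-values are computed; the statistic is a raw
percentage by design.

## Synthetic data

The generators emulate the statistical shape the analysis assumes, not any
particular dataset. Defaults: 500 genes, 20 samples per group, 10% of genes
with a planted group-mean shift of ±2.0 log₂ units (sign Bernoulli(0.5),
recorded in the truth object), per-cell Gaussian noise with sd 0.5 on the
log₂ scale, baseline gene means N(8, 1.5). At these settings the
fold-change rule recovers ≥ 90% of planted genes at a false-positive rate
≤ 0.05 (the t statistic of the shift is ≈ 2.0/(0.5·√(2/20)) ≈ 12.6, so the
binding constraint is the fold-change estimate, sd ≈ 0.16, giving ~3σ
margin at the 1.5 cutoff). The interactome is Barabási–Albert preferential
attachment (m = 2 by default); the miRNA layer samples a fixed number of
distinct targets per miRNA; complexes are uniformly sampled overlapping
subsets; drugs get a fixed number of gene targets each. One integer seed
feeds one named RNG stream per generator, so the layers are mutually
independent and byte-reproducible.

What the synthetic data does *not* emulate: probe-level array structure and
normalization artifacts, correlated noise between genes outside the planted
modules used in the co-expression tests, realistic miRNA target-set sizes
or sequence-based targeting, complex-size distributions of curated
catalogs, and any real gene identity. Passing tests therefore demonstrate
algorithmic correctness and calibration under the stated noise model, not
biological validity on array data.

## Numerical and design choices

- Fold-change (1.5) and edge-weight (0.05) constants live only in
  `PipelineConfig` / stage defaults, never hard-coded mid-stage.
- Determinism everywhere: lexicographic node order drives matchings,
  branch and bound, ranking tie-breaks, and eigenvector signs; the JSON
  report is written with sorted keys and contains no timestamps, so
  identical (config, seed) runs are byte-identical.
- The pipeline report schema is versioned (`schema_version: 1`).
- Zero-variance genes: correlations set to 0 with a warning, not an abort.
- The bundled demo configuration analyzes a ~180-node merged network
  (50 selected genes plus first-order interactome neighbors and active
  miRNAs), a size at which every stage, including per-arc link
  classification, completes in seconds.

## Known limitations

- Matching-based classification on bidirected layers concentrates
  criticality on source nodes; the link-derived promotion above is the
  package's documented answer, not a universally standard convention.
- Exact MDS mode does not scale past tens of nodes; no heuristic fallback
  is silently substituted.
- Directed (non-symmetric) spectra, weighted betweenness, signed
  co-expression, module detection, and enrichment statistics are out of
  scope.
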