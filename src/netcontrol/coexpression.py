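"""Weighted co-expression network construction.

Follows the weighted-network recipe: raise absolute Pearson correlations to a
soft-threshold power beta chosen so the weighted degree distribution is
approximately scale-free, convert the adjacency to topological-overlap (TOM)
edge weights, and keep pairs whose TOM weight clears a cutoff (default 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import Edge, Node, TypedNetwork
from .synthdata import ExpressionMatrix

DEFAULT_WEIGHT_CUTOFF = 0.05


@dataclass
class CoexpressionConfig:
    beta: int | None = None                       # fixed power; None = pick from grid
    beta_grid: list[int] = field(default_factory=lambda: list(range(1, 21)))
    r2_target: float = 0.8
    weight_cutoff: float = DEFAULT_WEIGHT_CUTOFF
    correlation: str = "unsigned_abs"

    def __post_init__(self) -> None:
        if self.correlation != "unsigned_abs":
            raise ValueError("only unsigned absolute correlation is supported")
        if not 0.0 <= self.weight_cutoff <= 1.0:
            raise ValueError("weight_cutoff must lie in [0, 1]")
        if not 0.0 < self.r2_target < 1.0:
            raise ValueError("r2_target must lie in (0, 1)")


def soft_adjacency(expr: ExpressionMatrix, beta: float) -> np.ndarray:
    """a_ij = |cor(g_i, g_j)|^beta with zero diagonal.

    Zero-variance genes get zero correlations (with a warning) rather than
    aborting the run.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if expr.values.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    values = expr.values
    flat = values.std(axis=1) == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s); their correlations set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.nan_to_num(corr, nan=0.0)
    adj = np.abs(corr) ** beta
    adj = np.clip(adj, 0.0, 1.0)
    np.fill_diagonal(adj, 0.0)
    return (adj + adj.T) / 2.0


def scale_free_fit(degrees: np.ndarray | list[float], n_bins: int = 10) -> float:
    """R^2 of the log-log degree-distribution fit.

    Connectivities are grouped into ``n_bins`` equal-occupancy bins; the
    squared correlation of log10(mean frequency) against log10(mean
    connectivity) over the non-empty bins is returned. All-equal degrees give
    an undefined fit, returned as 0 with a warning.
    """
    k = np.asarray(degrees, dtype=float)
    k = k[k > 0]
    if k.size < 5:
        raise ValueError("need at least 5 nodes with positive degree")
    if np.allclose(k, k[0]):
        warnings.warn("all degrees equal; scale-free fit undefined, returning 0",
                      stacklevel=2)
        return 0.0
    # equal-occupancy bin edges (duplicate quantiles collapsed); frequency is
    # a density, count / (n * bin width), so the log-log slope estimates the
    # power-law exponent
    edges = np.unique(np.quantile(k, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 3:
        warnings.warn("degenerate binning; scale-free fit undefined, returning 0",
                      stacklevel=2)
        return 0.0
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, edges.size - 2)
    x, y = [], []
    for b in range(edges.size - 1):
        mask = idx == b
        count = int(mask.sum())
        width = edges[b + 1] - edges[b]
        if count == 0 or width <= 0:
            continue
        mean_k = k[mask].mean()
        density = count / (k.size * width)
        if mean_k > 0 and density > 0:
            x.append(np.log10(mean_k))
            y.append(np.log10(density))
    if len(x) < 3 or np.unique(x).size < 2 or np.unique(y).size < 2:
        warnings.warn("degenerate binning; scale-free fit undefined, returning 0",
                      stacklevel=2)
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def pick_soft_threshold(expr: ExpressionMatrix, config: CoexpressionConfig) -> tuple[int, bool]:
    """Smallest beta in the grid whose weighted-degree distribution reaches the
    R^2 target; falls back to the argmax-R^2 beta with ``reached=False``."""
    if not config.beta_grid:
        raise ValueError("beta_grid must be nonempty")
    best_beta, best_r2 = config.beta_grid[0], -1.0
    for beta in config.beta_grid:
        adj = soft_adjacency(expr, beta)
        r2 = scale_free_fit(adj.sum(axis=0))
        if r2 >= config.r2_target:
            return beta, True
        if r2 > best_r2:
            best_beta, best_r2 = beta, r2
    warnings.warn(
        f"no beta in grid reached R2 target {config.r2_target}; "
        f"using argmax beta={best_beta} (R2={best_r2:.3f})",
        stacklevel=2,
    )
    return best_beta, False


def tom_weights(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (sum_u a_iu a_uj + a_ij) /
    (min(k_i, k_j) + 1 - a_ij), TOM_ii = 1."""
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any((a < 0) | (a > 1)):
        raise ValueError("adjacency entries must lie in [0, 1]")
    if np.any(np.diagonal(a) != 0):
        raise ValueError("adjacency diagonal must be zero")
    k = a.sum(axis=0)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return tom


def build_coexpression_network(
    expr: ExpressionMatrix, config: CoexpressionConfig | None = None
) -> tuple[TypedNetwork, dict]:
    """Full pipeline: soft threshold -> adjacency -> TOM -> cutoff.

    Returns the undirected gene-layer network (edge weight = TOM value) and a
    small info record (beta used, scale-free R^2, cutoff).
    """
    config = config or CoexpressionConfig()
    if len(expr.gene_ids) == 0:
        return TypedNetwork(), {"beta": None, "r2": None,
                                "weight_cutoff": config.weight_cutoff}
    if config.beta is not None:
        beta, reached = int(config.beta), True
    else:
        beta, reached = pick_soft_threshold(expr, config)
    adj = soft_adjacency(expr, beta)
    r2 = scale_free_fit(adj.sum(axis=0)) if len(expr.gene_ids) >= 5 else None
    tom = tom_weights(adj)

    net = TypedNetwork()
    for gid in expr.gene_ids:
        net.add_node(Node(gid, "gene"))
    n = len(expr.gene_ids)
    for i in range(n):
        for j in range(i + 1, n):
            w = float(tom[i, j])
            if w >= config.weight_cutoff:
                net.add_edge(
                    Edge(expr.gene_ids[i], expr.gene_ids[j], "coexpression",
                         directed=False, weight=w)
                )
    info = {"beta": beta, "r2_target_reached": reached, "r2": r2,
            "weight_cutoff": config.weight_cutoff}
    return net, info
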