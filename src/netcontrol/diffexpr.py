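"""Two-group differential expression on log2-scale intensities.

Per gene: log2 fold change (group A mean minus group B mean — a ratio of
intensities on the raw scale), a Welch unequal-variance t-test, and
Benjamini–Hochberg FDR adjustment across genes. Selection applies the
absolute fold-change cutoff (default |log2FC| >= 1.5); an FDR threshold is
optional because fold change alone defines the default selection rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthdata import ExpressionMatrix

DEFAULT_FC_CUTOFF = 1.5


@dataclass
class DEGRecord:
    gene: str
    log2fc: float
    p: float
    q: float
    selected: bool = False
    direction: str = "none"


def compute_logfc(expr: ExpressionMatrix) -> dict[str, float]:
    """log2FC(g) = mean log2 intensity in group A minus mean in group B."""
    a = expr.group_columns("A")
    b = expr.group_columns("B")
    if a.shape[1] < 1 or b.shape[1] < 1:
        raise ValueError("each group needs at least one sample")
    lfc = a.mean(axis=1) - b.mean(axis=1)
    return dict(zip(expr.gene_ids, lfc.astype(float)))


def test_and_adjust(
    expr: ExpressionMatrix, method: str = "fdr_bh"
) -> dict[str, tuple[float, float]]:
    """Welch two-sample test per gene with multiple-test adjustment.

    ``method`` is 'fdr_bh' (default) or 'bonferroni'. Genes with zero
    variance in both groups get p = 1 when the group means are equal
    (degenerate-case convention) and p = 0 otherwise, so pipelines never
    abort on flat synthetic genes.
    """
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError(f"unknown adjustment method {method!r}")
    a = expr.group_columns("A")
    b = expr.group_columns("B")
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least two samples")

    with np.errstate(all="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p = np.where(degenerate & equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, 0.0, p)
    if np.any(np.isnan(p)):
        raise ValueError("test produced NaN p-values on non-degenerate input")

    _, q, _, _ = multipletests(p, method=method)
    return {g: (float(pi), float(qi)) for g, pi, qi in zip(expr.gene_ids, p, q)}


def build_records(expr: ExpressionMatrix, method: str = "fdr_bh") -> list[DEGRecord]:
    lfc = compute_logfc(expr)
    pq = test_and_adjust(expr, method=method)
    return [DEGRecord(g, lfc[g], *pq[g]) for g in expr.gene_ids]


def select_degs(
    records: list[DEGRecord],
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    q_cutoff: float | None = None,
) -> list[DEGRecord]:
    """Apply the selection rule: |log2FC| >= fc_cutoff (inclusive), optionally
    AND q <= q_cutoff. Returns new records with selected/direction filled."""
    if fc_cutoff <= 0:
        raise ValueError("fc_cutoff must be positive")
    out: list[DEGRecord] = []
    for r in records:
        passes_fc = abs(r.log2fc) >= fc_cutoff
        passes_q = True if q_cutoff is None else r.q <= q_cutoff
        selected = passes_fc and passes_q
        if selected:
            direction = "up" if r.log2fc >= fc_cutoff else "down"
        else:
            direction = "none"
        out.append(DEGRecord(r.gene, r.log2fc, r.p, r.q, selected, direction))
    return out


def selected_ids(records: list[DEGRecord]) -> list[str]:
    return [r.gene for r in records if r.selected]


def records_to_frame(records: list[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                gene=r.gene,
                log2fc=r.log2fc,
                p=r.p,
                q=r.q,
                selected=r.selected,
                direction=r.direction,
            )
            for r in records
        ]
    )
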