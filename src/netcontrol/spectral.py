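"""Eigen-decomposition and participation-ratio localization analysis.

For a symmetric network matrix (adjacency or combinatorial Laplacian D - A)
the eigenvalues are sorted descending, lambda_1 = lambda_max >= ... >=
lambda_n, with L2-normalized eigenvectors. The inverse participation ratio
of a unit vector, IPR = sum_i e_i^4, measures localization: 1 when all mass
sits on one component, 1/n when the components are identically weighted.
PR = 1/IPR is the effective number of contributing components.

A second convention divides components by the largest-magnitude one before
summing fourth powers; its values can exceed 1 and it is provided for
reproduction of reports that used such a normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import TypedNetwork

UNIT_TOL = 1e-9


@dataclass
class SpectralResult:
    matrix_kind: str                  # "adjacency" or "laplacian"
    node_ids: list[str]
    eigenvalues: np.ndarray           # sorted descending
    eigenvectors: np.ndarray          # column i pairs with eigenvalues[i]
    convention: str = "l2"

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def ipr(self, index: int) -> float:
        return inverse_participation_ratio(self.eigenvectors[:, index],
                                           self.convention)

    def pr(self, index: int) -> float:
        return participation_ratio(self.eigenvectors[:, index])

    def principal(self) -> tuple[float, np.ndarray]:
        return float(self.eigenvalues[0]), self.eigenvectors[:, 0]

    def degenerate_flags(self, tol: float = 1e-8) -> np.ndarray:
        """True where an eigenvalue is within ``tol`` of a neighbor: the
        per-vector IPR inside such a subspace is basis-dependent."""
        lam = self.eigenvalues
        flags = np.zeros(len(lam), dtype=bool)
        close = np.abs(np.diff(lam)) <= tol
        flags[:-1] |= close
        flags[1:] |= close
        return flags


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude component positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def eigendecompose(
    network: TypedNetwork | nx.Graph,
    matrix_kind: str = "adjacency",
    weighted: bool = False,
    convention: str = "l2",
) -> SpectralResult:
    """Full symmetric eigendecomposition of the undirected simple view."""
    if matrix_kind not in ("adjacency", "laplacian"):
        raise ValueError(f"unknown matrix kind {matrix_kind!r}")
    g = network.to_undirected_nx() if isinstance(network, TypedNetwork) else network
    if g.number_of_nodes() < 1:
        raise ValueError("network must be nonempty")
    nodes = sorted(g.nodes)
    weight = "weight" if weighted else None
    a = nx.to_numpy_array(g, nodelist=nodes, weight=weight)
    if matrix_kind == "laplacian":
        m = np.diag(a.sum(axis=1)) - a
    else:
        m = a
    eigenvalues, eigenvectors = np.linalg.eigh(m)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    eigenvectors = _fix_signs(eigenvectors[:, order])
    return SpectralResult(matrix_kind, nodes, eigenvalues, eigenvectors, convention)


def participation_ratio(vector: np.ndarray) -> float:
    """PR = 1 / sum(e_i^4) for a unit-L2 vector; ranges over [1, n]."""
    v = np.asarray(vector, dtype=float)
    norm = np.linalg.norm(v)
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"vector must be unit L2 norm (got {norm:.6g}); "
                         "normalize before calling")
    return float(1.0 / np.sum(v**4))


def inverse_participation_ratio(vector: np.ndarray, convention: str = "l2") -> float:
    """IPR of an eigenvector.

    l2: sum of fourth powers of the L2-normalized components, in [1/n, 1].
    max_component: components are first divided by the largest-magnitude
    component, then the mean fourth power is taken; values may exceed 1.
    """
    v = np.asarray(vector, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("zero vector has no participation ratio")
    if convention == "l2":
        u = v / norm
        return float(np.sum(u**4))
    if convention == "max_component":
        u = v / v[np.argmax(np.abs(v))]
        return float(np.sum(u**4) / len(u))
    raise ValueError(f"unknown convention {convention!r}")


def localization_class(ipr: float, n: int, ratio_threshold: float = 10.0) -> str:
    """'localized' when the mass sits on roughly <= n/threshold components
    (ipr * n >= threshold under the l2 convention), else 'delocalized'."""
    return "localized" if ipr * n >= ratio_threshold else "delocalized"


def lowest_nonzero_eigen(
    result: SpectralResult, zero_tol: float = 1e-9
) -> tuple[float, np.ndarray, float]:
    """Smallest-magnitude eigenvalue above ``zero_tol`` with its eigenvector
    and IPR; communities of weakly coupled groups show up here as localized
    low-lying modes."""
    lam = result.eigenvalues
    mags = np.abs(lam)
    candidates = np.where(mags > zero_tol)[0]
    if candidates.size == 0:
        raise ValueError("all eigenvalues are within tolerance of zero")
    idx = candidates[np.argmin(mags[candidates])]
    vec = result.eigenvectors[:, idx]
    return float(lam[idx]), vec, inverse_participation_ratio(vec, result.convention)


def spectrum_table(result: SpectralResult, ratio_threshold: float = 10.0):
    """Per-eigenvector summary rows (index, eigenvalue, pr, ipr, class)."""
    import pandas as pd

    rows = []
    for i in range(result.n):
        ipr = result.ipr(i)
        rows.append(
            dict(
                index=i,
                eigenvalue=float(result.eigenvalues[i]),
                pr=1.0 / ipr if result.convention == "l2" else float("nan"),
                ipr=ipr,
                localization=localization_class(ipr, result.n, ratio_threshold)
                if result.convention == "l2"
                else "n/a",
            )
        )
    return pd.DataFrame(rows)
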