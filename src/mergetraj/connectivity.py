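"""Per-subject functional connectivity graphs.

A subject's node-by-time matrix is turned into a weighted functional graph in
three steps: pairwise Pearson correlation with parametric two-sided p-values,
Benjamini-Hochberg FDR thresholding over the unique node pairs with removal of
negative correlations, and a Fisher z-transform of the surviving coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TimeSeriesPanel",
    "WeightedGraph",
    "correlation_graph",
    "bh_reject",
    "fdr_threshold",
    "fisher_z",
    "subject_graph",
]


@dataclass
class TimeSeriesPanel:
    """One subject's multivariate time series (nodes x timepoints)."""

    subject_id: str
    data: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (nodes x time)")
        if self.data.shape[0] != len(self.node_ids):
            raise ValueError("node_ids length must match number of rows")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node ids must be unique")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if np.isnan(self.data).any():
            raise ValueError("missing values in time series")


@dataclass
class WeightedGraph:
    """Symmetric nonnegative weighted graph over named nodes.

    ``weights`` holds the retained edge strengths (Fisher-z units after the
    full pipeline); the raw correlation and p matrices are kept for
    provenance when available.
    """

    node_ids: list[str]
    weights: np.ndarray
    r: np.ndarray | None = None
    p: np.ndarray | None = None
    q_level: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.node_ids)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape must match node ids")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1) > 0))


def correlation_graph(panel: TimeSeriesPanel) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson r and two-sided p matrices for one subject.

    p-values come from the exact t transform ``t = r*sqrt((n-2)/(1-r^2))``
    with n-2 degrees of freedom (n = number of timepoints).
    """
    x = panel.data
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [panel.node_ids[i] for i in dead[:5]]
        raise ValueError(f"zero-variance node(s): {names}")
    n_t = x.shape[1]
    r = np.corrcoef(x)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    # t-test of r; collinear pairs (|r|=1) get p=0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n_t - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n_t - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    np.fill_diagonal(p, 0.0)
    p = (p + p.T) / 2.0  # enforce exact symmetry
    return r, p


def bh_reject(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg rejection mask for a flat p-value vector.

    Rejects the k smallest p-values where k is the largest index with
    ``p_(k) <= k*q/m``.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    crit = q * np.arange(1, m + 1) / m
    below = np.flatnonzero(sorted_p <= crit)
    mask = np.zeros(m, dtype=bool)
    if below.size:
        mask[order[: below[-1] + 1]] = True
    return mask


def fdr_threshold(
    p_matrix: np.ndarray,
    r_matrix: np.ndarray,
    q: float,
    node_ids: list[str] | None = None,
) -> WeightedGraph:
    """Keep edges that survive BH-FDR over the upper triangle AND have r>0."""
    if not (0.0 < q < 1.0):
        raise ValueError(f"q must be in (0,1), got {q}")
    p_matrix = np.asarray(p_matrix, dtype=float)
    r_matrix = np.asarray(r_matrix, dtype=float)
    if p_matrix.shape != r_matrix.shape:
        raise ValueError("p and r matrices must have the same shape")
    n = p_matrix.shape[0]
    if node_ids is None:
        node_ids = [str(i) for i in range(n)]
    iu = np.triu_indices(n, k=1)
    keep = bh_reject(p_matrix[iu], q) & (r_matrix[iu] > 0)
    w = np.zeros((n, n), dtype=float)
    w[iu[0][keep], iu[1][keep]] = r_matrix[iu][keep]
    w = w + w.T
    return WeightedGraph(node_ids=list(node_ids), weights=w, r=r_matrix, p=p_matrix, q_level=q)


def fisher_z(graph: WeightedGraph) -> WeightedGraph:
    """Fisher z-transform (atanh) of retained correlation weights.

    Monotone, so the descending-strength merge schedule is unchanged;
    off-diagonal weights of 1 (perfectly collinear nodes) are rejected.
    """
    w = graph.weights
    if np.any(w >= 1.0):
        raise ValueError("off-diagonal weight >= 1; collinear nodes must be handled upstream")
    return WeightedGraph(
        node_ids=list(graph.node_ids),
        weights=np.arctanh(w),
        r=graph.r,
        p=graph.p,
        q_level=graph.q_level,
    )


def subject_graph(panel: TimeSeriesPanel, q: float = 0.001) -> WeightedGraph:
    """Full per-subject pipeline: correlate, FDR-threshold, Fisher-z."""
    r, p = correlation_graph(panel)
    return fisher_z(fdr_threshold(p, r, q, node_ids=panel.node_ids))
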