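"""Merging-trajectory analysis: graph coarsening toward the minimal graph.

The coarsening rule compares, for an adjacent pair of (super-)nodes, the
weighted degree of their shared links (links to common neighbors, counted
from both endpoints) against the weighted degree of their distinct links
(links to neighbors adjacent to exactly one of the pair). If shared exceeds
distinct the pair is merged; the merged super-node's connectivity to any
neighbor is the mean strength over all original member pairs, counting
absent original links as zero. Edges are visited in descending weight and
the sweep restarts from the strongest live edge after every merge, until a
full sweep yields no merge (the minimal graph).

Each original node's cluster-size growth curve c_v over merging time is
then fit by a logarithmic and an exponential model. Merging time is the
position in the descending-strength schedule: event k happening at merged
link weight w_k occurs at t_k = (w_max - w_k)/(w_max - w_min), so strong
(early) links sit near t=0 and weak (late) links near t=1. Nodes whose
growth is better explained by the logarithmic curve merge early
(*segregators*); nodes better explained by the exponential curve merge
late (*integrators*).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import WeightedGraph

__all__ = [
    "MergeEvent",
    "MergeTrajectory",
    "NodeClassification",
    "PhenotypeMap",
    "evaluate_pair",
    "pair_degrees",
    "run_merging",
    "random_rule_baseline",
    "merge_times",
    "fit_trajectory_models",
    "group_maps",
    "group_classification",
]


@dataclass(frozen=True)
class MergeEvent:
    """One merge: event index k (1-based), the two representative node ids
    of the merged pair, the weight of the merged link, and the resulting
    super-node's member ids."""

    k: int
    rep_a: str
    rep_b: str
    weight: float
    members: tuple[str, ...]


@dataclass
class MergeTrajectory:
    node_ids: list[str]
    events: list[MergeEvent]
    final_members: list[tuple[str, ...]]  # live super-nodes of the minimal graph
    final_weights: np.ndarray  # minimal-graph weight matrix over final_members

    @property
    def n_events(self) -> int:
        return len(self.events)

    def growth_curves(self) -> np.ndarray:
        """(n, K+1) matrix: c_v(k) = size of v's super-node after event k.

        Column 0 is the initial state (every node is its own super-node).
        """
        n = len(self.node_ids)
        idx = {v: i for i, v in enumerate(self.node_ids)}
        curves = np.ones((n, self.n_events + 1), dtype=float)
        cur = np.ones(n, dtype=float)
        for ev in self.events:
            rows = [idx[v] for v in ev.members]
            cur[rows] = len(ev.members)
            curves[:, ev.k] = cur
        return curves


def pair_degrees(weights: np.ndarray, u: int, v: int) -> tuple[float, float]:
    """Shared and distinct weighted degree for adjacent pair (u, v).

    Shared counts both endpoints' links to every common neighbor; distinct
    counts the single link to every neighbor of exactly one endpoint. The
    (u, v) edge itself contributes to neither sum.
    """
    if weights[u, v] <= 0:
        raise ValueError(f"pair ({u}, {v}) is not adjacent")
    wu = weights[u].copy()
    wv = weights[v].copy()
    wu[[u, v]] = 0.0
    wv[[u, v]] = 0.0
    nu = wu > 0
    nv = wv > 0
    common = nu & nv
    shared = float(wu[common].sum() + wv[common].sum())
    distinct = float(wu[nu & ~nv].sum() + wv[nv & ~nu].sum())
    return shared, distinct


def evaluate_pair(weights: np.ndarray, u: int, v: int) -> tuple[bool, float, float]:
    """Merge decision for an adjacent pair: merge iff shared > distinct."""
    shared, distinct = pair_degrees(weights, u, v)
    return shared > distinct, shared, distinct


def _coarsen(
    graph: WeightedGraph,
    choose_random: np.random.Generator | None = None,
) -> MergeTrajectory:
    """Shared engine for the merge rule and the random baseline."""
    n = graph.n_nodes
    node_ids = list(graph.node_ids)
    W = graph.weights.astype(float).copy()
    live = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=int)
    members: list[set[int]] = [{i} for i in range(n)]
    events: list[MergeEvent] = []

    def do_merge(i: int, j: int) -> None:
        w_edge = float(W[i, j])
        rep, other = (i, j) if i < j else (j, i)
        si, sj = sizes[i], sizes[j]
        row = (si * W[i] + sj * W[j]) / (si + sj)
        row[rep] = 0.0
        row[other] = 0.0
        W[rep, :] = row
        W[:, rep] = row
        W[other, :] = 0.0
        W[:, other] = 0.0
        live[other] = False
        sizes[rep] = si + sj
        members[rep] |= members[other]
        new_members = tuple(node_ids[x] for x in sorted(members[rep]))
        events.append(
            MergeEvent(
                k=len(events) + 1,
                rep_a=node_ids[min(i, j)],
                rep_b=node_ids[max(i, j)],
                weight=w_edge,
                members=new_members,
            )
        )

    if choose_random is not None:
        # random baseline: merge a uniformly chosen live edge, unconditionally
        while True:
            ii, jj = np.nonzero(np.triu(W, k=1) > 0)
            if ii.size == 0:
                break
            pick = int(choose_random.integers(ii.size))
            do_merge(int(ii[pick]), int(jj[pick]))
    else:
        # descending-strength sweep, restarted from the strongest live edge
        # after every merge so a growing super-node keeps absorbing while
        # its (mean-strength) links stay the strongest
        while True:
            ii, jj = np.nonzero(np.triu(W, k=1) > 0)
            if ii.size == 0:
                break
            w_snap = W[ii, jj]
            order = np.lexsort((jj, ii, -w_snap))
            merged = False
            for e in order:
                i, j = int(ii[e]), int(jj[e])
                merge, _, _ = evaluate_pair(W, i, j)
                if merge:
                    do_merge(i, j)
                    merged = True
                    break
            if not merged:
                break

    final_idx = [i for i in range(n) if live[i]]
    final_members = [tuple(node_ids[x] for x in sorted(members[i])) for i in final_idx]
    final_weights = W[np.ix_(final_idx, final_idx)]
    return MergeTrajectory(
        node_ids=node_ids,
        events=events,
        final_members=final_members,
        final_weights=final_weights,
    )


def run_merging(graph: WeightedGraph) -> MergeTrajectory:
    """Coarsen a graph to its minimal graph under the shared-vs-distinct rule.

    Deterministic: live edges are visited in descending weight (ties broken
    by (min node index, max node index)); after every merge the sweep
    restarts from the strongest live edge, so the merged super-node's new
    mean-strength links compete immediately. The process stops when a full
    sweep yields no merge (the minimal graph).
    """
    return _coarsen(graph, choose_random=None)


def random_rule_baseline(graph: WeightedGraph, seed: int) -> MergeTrajectory:
    """Merge uniformly random adjacent pairs; comparison baseline only."""
    return _coarsen(graph, choose_random=np.random.default_rng(seed))


@dataclass
class NodeClassification:
    """Per-node logarithmic vs exponential trajectory fits.

    ``score = r2_log - r2_exp``; positive scores label a node *segregator*
    (early merger), negative *integrator* (late merger). Nodes that never
    merge have undefined fits and stay ``unclassified``.
    """

    node_ids: list[str]
    r2_log: np.ndarray
    r2_exp: np.ndarray
    coef_log: np.ndarray  # (n, 2): y = a + b*ln(t + eps)
    coef_exp: np.ndarray  # (n, 2): y = a * exp(b*t)
    score: np.ndarray
    labels: np.ndarray  # 'segregator' | 'integrator' | 'unclassified'


def _r2(y: np.ndarray, yhat: np.ndarray) -> np.ndarray:
    ss_res = ((y - yhat) ** 2).sum(axis=1)
    ss_tot = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    r2 = np.where(ss_tot == 0, np.nan, r2)
    return np.clip(r2, 0.0, 1.0)


def merge_times(traj: MergeTrajectory) -> np.ndarray:
    """Normalized merging time of each event from its link strength.

    t_k = (w_max - w_k)/(w_max - w_min) over the merged link weights, so
    the strongest merged link defines t=0 and the weakest t=1 (clipped for
    the occasional non-monotone mean-strength link). Degenerate case (all
    merged weights equal) falls back to the event index k/K.
    """
    K = traj.n_events
    w = np.array([ev.weight for ev in traj.events], dtype=float)
    if K == 0:
        return w
    lo, hi = w.min(), w.max()
    if hi == lo:
        return np.arange(1, K + 1) / K
    return np.clip((hi - w) / (hi - lo), 0.0, 1.0)


def fit_trajectory_models(traj: MergeTrajectory) -> NodeClassification:
    """Fit log and exp growth models to every node's cluster-size curve.

    With K merge events at merging times t_k (descending-strength position,
    see :func:`merge_times`) and cluster size y = c_v(k)/n, the log model
    y = a + b*ln(t + 1/K) is ordinary least squares; the exponential
    y = a*exp(b*t) is fit log-linearly with R^2 re-evaluated on the
    original y scale.
    """
    K = traj.n_events
    if K < 3:
        raise ValueError(f"need at least 3 merge events to fit trajectories, got {K}")
    n = len(traj.node_ids)
    y = traj.growth_curves()[:, 1:] / n  # (n, K), y in (0, 1]
    t = merge_times(traj)
    eps = 1.0 / K

    X_log = np.column_stack([np.ones(K), np.log(t + eps)])
    beta_log, *_ = np.linalg.lstsq(X_log, y.T, rcond=None)
    r2_log = _r2(y, (X_log @ beta_log).T)

    X_exp = np.column_stack([np.ones(K), t])
    beta_ln, *_ = np.linalg.lstsq(X_exp, np.log(y).T, rcond=None)
    r2_exp = _r2(y, np.exp(X_exp @ beta_ln).T)
    coef_exp = np.column_stack([np.exp(beta_ln[0]), beta_ln[1]])

    score = r2_log - r2_exp
    labels = np.where(score > 0, "segregator", np.where(score < 0, "integrator", "unclassified"))
    labels = np.where(np.isnan(score), "unclassified", labels)
    return NodeClassification(
        node_ids=list(traj.node_ids),
        r2_log=r2_log,
        r2_exp=r2_exp,
        coef_log=beta_log.T,
        coef_exp=coef_exp,
        score=np.where(np.isnan(score), 0.0, score),
        labels=labels,
    )


@dataclass
class PhenotypeMap:
    """One scalar per region/node (segregation, integration, or S - I)."""

    region_ids: list[str]
    values: np.ndarray
    kind: str = "S_minus_I"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.region_ids) != self.values.size:
            raise ValueError("one value per region required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map values must be finite")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("region ids must be unique")


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def group_maps(
    classifications: list[NodeClassification],
) -> tuple[PhenotypeMap, PhenotypeMap, PhenotypeMap]:
    """Subject-normalized group segregation (S), integration (I) and S-I maps.

    Each subject's R^2_log and R^2_exp vectors are min-max normalized to
    [0, 1] (undefined fits enter as 0); group maps are element-wise means.
    """
    if not classifications:
        raise ValueError("no classifications given")
    ids = classifications[0].node_ids
    for c in classifications:
        if c.node_ids != ids:
            raise ValueError("all subjects must share node ids")
    s_stack = np.array([_minmax(np.nan_to_num(c.r2_log)) for c in classifications])
    i_stack = np.array([_minmax(np.nan_to_num(c.r2_exp)) for c in classifications])
    s = s_stack.mean(axis=0)
    i = i_stack.mean(axis=0)
    return (
        PhenotypeMap(list(ids), s, "S"),
        PhenotypeMap(list(ids), i, "I"),
        PhenotypeMap(list(ids), s - i, "S_minus_I"),
    )


def group_classification(classifications: list[NodeClassification]) -> np.ndarray:
    """Group-level node labels from the subject-averaged score.

    Averaging s_v = R^2_log - R^2_exp across subjects before taking the
    sign absorbs subject-level noise in the merge schedule.
    """
    if not classifications:
        raise ValueError("no classifications given")
    ids = classifications[0].node_ids
    for c in classifications:
        if c.node_ids != ids:
            raise ValueError("all subjects must share node ids")
    mean_s = np.mean([c.score for c in classifications], axis=0)
    labels = np.where(mean_s > 0, "segregator", np.where(mean_s < 0, "integrator", "unclassified"))
    return labels
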