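"""Independent brute-force reference implementations used as test oracles.

Everything here recomputes from first principles (original weight matrix,
explicit hypergeometric enumeration, definitional BH scan) with no code
shared with the package paths under test.
"""

from __future__ import annotations

from math import comb

import numpy as np


def brute_force_merge_events(weights: np.ndarray) -> list[tuple[frozenset, frozenset]]:
    """Reference coarsening: recompute every super-node weight from the
    original matrix at every step.

    Super-node pair weight = mean of original weights over all member
    pairs (absent links count 0). Candidate edges are sorted by
    descending weight with ties broken by (min member index of the lower
    representative, min member index of the higher). The first adjacent
    pair whose shared weighted degree exceeds its distinct weighted
    degree is merged and the scan restarts; a scan with no merge ends the
    process. Returns the merged pair's member sets per event.
    """
    w0 = np.asarray(weights, dtype=float)
    n = w0.shape[0]
    groups: list[frozenset] = [frozenset([i]) for i in range(n)]
    events = []

    def pair_weight(a: frozenset, b: frozenset) -> float:
        total = 0.0
        for i in a:
            for j in b:
                total += w0[i, j]
        return total / (len(a) * len(b))

    while True:
        m = len(groups)
        wmat = np.zeros((m, m))
        for x in range(m):
            for y in range(x + 1, m):
                wmat[x, y] = wmat[y, x] = pair_weight(groups[x], groups[y])
        candidates = []
        for x in range(m):
            for y in range(x + 1, m):
                if wmat[x, y] > 0:
                    rx, ry = min(groups[x]), min(groups[y])
                    lo, hi = (x, y) if rx < ry else (y, x)
                    candidates.append((-wmat[x, y], min(groups[lo]), min(groups[hi]), lo, hi))
        candidates.sort()
        merged = False
        for _, _, _, x, y in candidates:
            shared = 0.0
            distinct = 0.0
            for z in range(m):
                if z in (x, y):
                    continue
                wx, wy = wmat[x, z], wmat[y, z]
                if wx > 0 and wy > 0:
                    shared += wx + wy
                elif wx > 0:
                    distinct += wx
                elif wy > 0:
                    distinct += wy
            if shared > distinct:
                events.append((groups[x], groups[y]))
                new = groups[x] | groups[y]
                groups = [g for k, g in enumerate(groups) if k not in (x, y)] + [new]
                merged = True
                break
        if not merged:
            break
    return events


def brute_force_bh(pvals, q: float) -> np.ndarray:
    """Definitional BH: reject the k smallest p's for the largest k with
    p_(k) <= k q / m."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_star]] = True
    return mask


def hypergeom_upper_tail(overlap: int, n_universe: int, n_term: int, n_sel: int) -> float:
    """P(X >= overlap) by explicit enumeration of hypergeometric mass."""
    denom = comb(n_universe, n_sel)
    total = 0
    for k in range(overlap, min(n_term, n_sel) + 1):
        total += comb(n_term, k) * comb(n_universe - n_term, n_sel - k)
    return total / denom
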