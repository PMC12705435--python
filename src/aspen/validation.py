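"""Independent brute-force reference implementations.

These deliberately naive routines exist to cross-check the optimized code
paths (streaming ES, KD-tree neighbor search, library-backed BH, IRLS
logistic fit).  They share no code with the implementations they validate.
"""

from __future__ import annotations

import numpy as np


def enrichment_score_dense(stats: np.ndarray, hit_mask: np.ndarray,
                           weight_exponent: float = 1.0) -> float:
    """ES by materializing the full N-step running sum."""
    stats = np.asarray(stats, dtype=float)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    n = stats.size
    k = int(hit_mask.sum())
    if k == 0 or k == n:
        raise ValueError("degenerate set")
    w = np.abs(stats) ** weight_exponent
    total = w[hit_mask].sum()
    steps = np.where(hit_mask, w / total, -1.0 / (n - k))
    running = np.cumsum(steps)
    r_max = float(running.max())
    r_min = float(running.min())
    # magnitude ties (within float accumulation error) resolve positive,
    # matching the streaming path
    if abs(r_max) >= abs(r_min) - 1e-12:
        return r_max
    return r_min


def bh_stepup(pvalues) -> np.ndarray:
    """Textbook Benjamini–Hochberg: sort, scale by m/rank, enforce monotone, unsort."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def fraction_within_radius_bruteforce(
    query_xy: np.ndarray,
    ref_xy: np.ndarray,
    radius: float,
    query_ids=None,
    ref_ids=None,
) -> float:
    """All-pairs Euclidean distance check, identity-based self exclusion."""
    q = np.asarray(query_xy, dtype=float)
    r = np.asarray(ref_xy, dtype=float)
    if q.shape[0] == 0:
        return np.nan
    if r.shape[0] == 0:
        return 0.0
    hits = 0
    for i in range(q.shape[0]):
        d = np.sqrt(((r - q[i]) ** 2).sum(axis=1))
        ok = d <= radius
        if query_ids is not None and ref_ids is not None:
            ok &= np.asarray(ref_ids) != query_ids[i]
        if ok.any():
            hits += 1
    return hits / q.shape[0]


def logistic_loglik(x: np.ndarray, y: np.ndarray, intercept: float, slope: float) -> float:
    eta = intercept + slope * np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def logistic_grid_mle(
    x, y, slope_range=(-20.0, 20.0), intercept_range=(-40.0, 40.0), n_coarse=201,
    n_refine: int = 4,
) -> tuple[float, float]:
    """Maximum-likelihood (intercept, slope) by iteratively refined grid search."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    b_lo, b_hi = slope_range
    a_lo, a_hi = intercept_range
    best = (0.0, 0.0)
    for _ in range(n_refine + 1):
        a_grid = np.linspace(a_lo, a_hi, n_coarse)
        b_grid = np.linspace(b_lo, b_hi, n_coarse)
        ll = np.array([[logistic_loglik(x, y, a, b) for b in b_grid] for a in a_grid])
        ia, ib = np.unravel_index(np.argmax(ll), ll.shape)
        best = (float(a_grid[ia]), float(b_grid[ib]))
        da = (a_hi - a_lo) / (n_coarse - 1)
        db = (b_hi - b_lo) / (n_coarse - 1)
        a_lo, a_hi = best[0] - 2 * da, best[0] + 2 * da
        b_lo, b_hi = best[1] - 2 * db, best[1] + 2 * db
    return best
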