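"""Weighted Kolmogorov–Smirnov enrichment scores with a gene-sampling permutation null.

The running-sum statistic walks a ranking of genes sorted by a signed score
(here: Pearson correlation of pseudobulk expression with age).  Hits add
|score|^p normalized by the in-set total; misses subtract 1/(N - N_set).
The enrichment score (ES) is the signed maximum deviation of the running sum
and the normalized score (NES) divides by the mean magnitude of same-sign
scores from random same-size gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import bh_adjust, welch_set_test


class DegenerateSetError(ValueError):
    """The member set covers the whole ranking universe (miss step undefined)."""


@dataclass
class ESResult:
    es: float
    leading_edge: list[str]
    hit_positions: np.ndarray  # 0-based positions of members in the ranking
    testable: bool = True


def _es_from_hits(
    weights_at_hits: np.ndarray, positions: np.ndarray, miss_step: float
) -> tuple[float, int]:
    """ES and extremum hit index from sorted 0-based hit positions.

    The running sum only attains candidate extrema immediately before or
    after a hit, so the full N-length walk is never materialized.
    """
    k = positions.size
    total = weights_at_hits.sum()
    if total == 0:
        # all member weights zero (|r|^p with p>0 and r==0 cannot occur here,
        # but guard anyway): pure miss walk
        return 0.0, 0
    cum = np.cumsum(weights_at_hits) / total
    drop = (positions - np.arange(k)) * miss_step
    tops = cum - drop  # value just after each hit
    bots = tops - weights_at_hits / total  # value just before each hit
    i_max = int(np.argmax(tops))
    i_min = int(np.argmin(bots))
    es_pos = float(tops[i_max])
    es_neg = float(bots[i_min])
    # magnitude ties (within float accumulation error) resolve positive
    if abs(es_pos) >= abs(es_neg) - 1e-12:
        return es_pos, i_max
    return es_neg, i_min


def enrichment_score(
    gene_ids: list[str],
    stats: np.ndarray,
    member_set,
    weight_exponent: float = 1.0,
) -> ESResult:
    """Streaming ES over a descending ranking, with the leading-edge genes.

    ``gene_ids``/``stats`` must already be sorted by descending statistic.
    An empty intersection yields a not-testable result; a set covering the
    entire universe raises (the miss denominator is zero).
    """
    stats = np.asarray(stats, dtype=float)
    n = stats.size
    members = set(member_set)
    hit_mask = np.fromiter((g in members for g in gene_ids), bool, count=n)
    positions = np.flatnonzero(hit_mask)
    k = positions.size
    if k == 0:
        return ESResult(np.nan, [], positions, testable=False)
    if k == n:
        raise DegenerateSetError("member set covers the entire ranking universe")
    weights = np.abs(stats[positions]) ** weight_exponent
    es, i_ext = _es_from_hits(weights, positions, 1.0 / (n - k))
    if es >= 0:
        lead = [gene_ids[p] for p in positions[: i_ext + 1]]
    else:
        lead = [gene_ids[p] for p in positions[i_ext:]]
    return ESResult(float(es), lead, positions)


@dataclass
class PermutationResult:
    p: float
    nes: float
    n_same_sign: int
    null_es: np.ndarray = field(repr=False, default=None)
    testable: bool = True


def sample_null_es(
    stats: np.ndarray,
    set_size: int,
    n_permutations: int,
    rng: np.random.Generator,
    weight_exponent: float = 1.0,
    chunk: int = 2048,
) -> np.ndarray:
    """ES of ``n_permutations`` random same-size gene sets (without replacement)."""
    stats = np.asarray(stats, dtype=float)
    n = stats.size
    k = int(set_size)
    if not 0 < k < n:
        raise ValueError("set size must satisfy 0 < k < universe size")
    w_all = np.abs(stats) ** weight_exponent
    miss = 1.0 / (n - k)
    out = np.empty(n_permutations)
    offsets = np.arange(k)
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        # m draws of k positions without replacement: partial argsort of noise
        noise = rng.random((m, n))
        pos = np.sort(np.argpartition(noise, k - 1, axis=1)[:, :k], axis=1)
        w = w_all[pos]
        totals = w.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        cum = np.cumsum(w, axis=1) / totals
        tops = cum - (pos - offsets) * miss
        bots = tops - w / totals
        es_pos = tops.max(axis=1)
        es_neg = bots.min(axis=1)
        out[done : done + m] = np.where(es_pos >= -es_neg - 1e-12, es_pos, es_neg)
        done += m
    return out


def permutation_pvalue(observed_es: float, null_es: np.ndarray) -> PermutationResult:
    """Signed-tail permutation p and NES for an observed ES.

    p = (1 + #{same-sign null with |null| >= |ES|}) / (1 + #{same-sign null});
    NES = ES / mean|same-sign null|.  With no same-sign nulls the statistic
    is not testable.
    """
    null_es = np.asarray(null_es, dtype=float)
    if not np.isfinite(observed_es):
        return PermutationResult(np.nan, np.nan, 0, null_es, testable=False)
    same = null_es >= 0 if observed_es >= 0 else null_es < 0
    n_same = int(same.sum())
    if n_same == 0:
        return PermutationResult(np.nan, np.nan, 0, null_es, testable=False)
    tail = int(np.sum(np.abs(null_es[same]) >= abs(observed_es)))
    p = (1.0 + tail) / (1.0 + n_same)
    nes = observed_es / np.mean(np.abs(null_es[same]))
    return PermutationResult(float(p), float(nes), n_same, null_es)


def preranked_gsea(
    ranking: dict[str, float] | "pd.Series",
    gene_sets,
    n_permutations: int = 10_000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    alpha: float = 0.05,
):
    """Enrichment table for an externally supplied named ranking.

    Applies the same ES / permutation / Welch / BH machinery used by the
    per-cell-type pipeline to e.g. a bulk log2-fold-change ranking.
    Gene names must be unique and statistics finite.  Null ES samples are
    shared across sets of equal size for a given seed.
    """
    import pandas as pd

    series = pd.Series(dict(ranking)) if not isinstance(ranking, pd.Series) else ranking
    if series.index.has_duplicates:
        raise ValueError("duplicate gene names in ranking")
    if not np.all(np.isfinite(series.to_numpy(dtype=float))):
        raise ValueError("ranking statistics must be finite")
    order = sorted(zip(-series.to_numpy(dtype=float), series.index))
    stats = np.array([-s for s, _ in order])
    genes = [g for _, g in order]
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name, members in gene_sets:
        res = enrichment_score(genes, stats, members, weight_exponent)
        if not res.testable:
            rows.append(
                dict(gene_set=name, es=np.nan, nes=np.nan, p_perm=np.nan,
                     p_param=np.nan, leading_edge="", n_members=0, testable=False)
            )
            continue
        k = res.hit_positions.size
        if k not in null_cache:
            null_cache[k] = sample_null_es(stats, k, n_permutations, rng, weight_exponent)
        perm = permutation_pvalue(res.es, null_cache[k])
        hit_mask = np.zeros(stats.size, dtype=bool)
        hit_mask[res.hit_positions] = True
        welch = welch_set_test(stats[hit_mask], stats[~hit_mask])
        rows.append(
            dict(gene_set=name, es=res.es, nes=perm.nes, p_perm=perm.p,
                 p_param=welch.p, leading_edge=";".join(res.leading_edge),
                 n_members=k, testable=perm.testable and welch.testable)
        )
    table = pd.DataFrame(rows)
    for col, adj in (("p_perm", "padj_perm"), ("p_param", "padj_param")):
        table[adj] = np.nan
        mask = table[col].notna()
        if mask.any():
            table.loc[mask, adj] = bh_adjust(table.loc[mask, col].to_numpy())
    table["significant"] = (table["padj_perm"] < alpha) & (table["padj_param"] < alpha)
    return table
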