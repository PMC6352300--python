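"""Kolmogorov–Smirnov-type set enrichment kernel.

This is the single statistic the pipeline applies twice: once to score a
pathway's genes against a drug's ranked gene list (building pathway
expression profiles), and once to score a query gene's pathway set against a
drug's ranked pathway list (ranking drugs). The enrichment score (ES) is the
signed extremum of the classic unweighted running sum: walking down the
ranked list, the sum gains 1/|S| at each member of the set S and loses
1/(N-|S|) at each non-member. ES lies in [-1, 1]; +1 means S occupies
exactly the top |S| positions (the set is maximally up-modulated), -1 means
exactly the bottom |S| positions.

Significance is assessed by permutation: random sets of the same size are
drawn uniformly without replacement from the list positions, and the
two-sided p-value is the add-one tail estimate on |ES|. Because the
unweighted ES depends on the ranked list only through the positions of the
hits, the null distribution is a function of (N, |S|) alone; callers that
score many cells share null draws per (N, |S|) through
:class:`PermutationNull`.
"""

from __future__ import annotations

import hashlib
import logging
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger("drugsea.enrichment")

__all__ = [
    "UndefinedScoreError",
    "derive_seed",
    "rng_for",
    "es_from_hits",
    "hit_positions",
    "enrichment_score",
    "enrichment_score_weighted",
    "sample_null_abs_es",
    "enrichment_pvalue",
    "bh_adjust",
    "PermutationNull",
]


class UndefinedScoreError(ValueError):
    """The enrichment score is undefined (empty set or set = whole list)."""


def derive_seed(*parts) -> int:
    """Stable sub-seed (< 2**31) from arbitrary labelled parts.

    blake2b of the ':'-joined string representation, so serial and parallel
    schedules, and repeated runs on any platform, agree bit for bit.
    """
    digest = hashlib.blake2b(
        ":".join(str(p) for p in parts).encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


def rng_for(*parts) -> np.random.Generator:
    return np.random.default_rng(derive_seed(*parts))


def es_from_hits(hits, n: int):
    """ES from 1-based hit positions within a ranked list of length ``n``.

    ``hits`` is a 1-D array of k positions, or a (B, k) array scoring B
    position sets at once (rows need not be pre-sorted). Vectorised closed
    form: the running sum attains its extrema only at a hit (maximum
    candidate) or immediately before one (minimum candidate), so only the
    hit positions matter. When the largest positive and negative deviations
    tie exactly, the positive value is returned.
    """
    h = np.asarray(hits)
    single = h.ndim == 1
    if single:
        h = h[None, :]
    k = h.shape[1]
    if k < 1 or k >= n:
        raise UndefinedScoreError(
            f"set size {k} undefined for a ranked list of length {n}"
        )
    h = np.sort(h.astype(np.int64), axis=1)
    i = np.arange(1, k + 1, dtype=np.int64)
    # running sum scaled by k*(n-k) is integer-valued, so extremum selection
    # (and the tie toward the positive side) is exact
    miss = (h - i) * k                       # misses seen before/at each hit
    at_hit = i * (n - k) - miss              # scaled sum at the hit
    before_hit = (i - 1) * (n - k) - miss    # scaled sum just before the hit
    pos = np.maximum(at_hit.max(axis=1), 0)
    neg = np.minimum(before_hit.min(axis=1), 0)
    es = np.where(pos >= -neg, pos, neg) / float(k * (n - k))
    return float(es[0]) if single else es


def hit_positions(ranked_items: Sequence[str], item_set: Iterable[str]) -> np.ndarray:
    """1-based positions of ``item_set`` members in the ranked list.

    Members absent from the list are dropped with a warning (pathway
    databases always annotate genes outside any given compendium).
    """
    index = {item: pos for pos, item in enumerate(ranked_items, start=1)}
    if len(index) != len(ranked_items):
        raise ValueError("ranked list contains duplicate items")
    wanted = set(item_set)
    present = [index[x] for x in wanted if x in index]
    missing = len(wanted) - len(present)
    if missing:
        log.warning("dropped %d set item(s) absent from the ranked list", missing)
    return np.sort(np.asarray(present, dtype=np.int64))


def enrichment_score(ranked_items: Sequence[str], item_set: Iterable[str]) -> float:
    """Unweighted KS enrichment score of ``item_set`` against a ranked list."""
    pos = hit_positions(ranked_items, item_set)
    n = len(ranked_items)
    if pos.size == 0:
        raise UndefinedScoreError("no set item appears in the ranked list")
    if pos.size == n:
        raise UndefinedScoreError("set covers the entire ranked list")
    return es_from_hits(pos, n)


def enrichment_score_weighted(
    ranked_items: Sequence[str],
    scores: Sequence[float],
    item_set: Iterable[str],
    exponent: float = 1.0,
) -> float:
    """Score-weighted running-sum variant (off by default in the pipeline).

    Hit increments are proportional to |score|**exponent of the item, as in
    weighted GSEA; misses still lose 1/(N-k). ``scores`` aligns with
    ``ranked_items``. exponent=0 recovers :func:`enrichment_score`.
    """
    n = len(ranked_items)
    pos = hit_positions(ranked_items, item_set)
    if pos.size == 0:
        raise UndefinedScoreError("no set item appears in the ranked list")
    if pos.size == n:
        raise UndefinedScoreError("set covers the entire ranked list")
    s = np.abs(np.asarray(scores, dtype=float)) ** exponent
    hit = np.zeros(n, dtype=bool)
    hit[pos - 1] = True
    w = s[pos - 1]
    if w.sum() == 0:
        w = np.ones_like(w)  # degenerate all-zero weights: fall back to flat
    steps = np.where(hit, 0.0, -1.0 / (n - pos.size))
    steps[pos - 1] = w / w.sum()
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def _random_hit_sets(rng: np.random.Generator, b: int, n: int, k: int) -> np.ndarray:
    """b uniform k-subsets of {1..n} as a (b, k) array of 1-based positions."""
    u = rng.random((b, n))
    return np.argpartition(u, k - 1, axis=1)[:, :k] + 1


def sample_null_abs_es(
    n: int, set_size: int, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Sorted |ES| values of ``n_permutations`` random sets of the given size."""
    out = np.empty(n_permutations)
    # chunk so the (b, n) uniform matrix stays modest in memory
    step = max(1, int(2_000_000 // max(n, 1)))
    for start in range(0, n_permutations, step):
        b = min(step, n_permutations - start)
        hits = _random_hit_sets(rng, b, n, set_size)
        out[start : start + b] = np.abs(es_from_hits(hits, n))
    out.sort()
    return out


def _tail_pvalues(null_sorted: np.ndarray, abs_es) -> np.ndarray:
    """Add-one two-sided tail: (1 + #{null >= obs}) / (B + 1)."""
    b = null_sorted.size
    ge = b - np.searchsorted(null_sorted, abs_es, side="left")
    return (1.0 + ge) / (b + 1.0)


def enrichment_pvalue(
    observed_es: float,
    ranked_list_length: int,
    set_size: int,
    n_permutations: int = 10_000,
    seed: int | None = None,
    method: str = "permutation",
) -> float:
    """Two-sided permutation p-value for an observed ES.

    ``method='permutation'`` draws ``n_permutations`` random sets (seeded);
    ``method='exhaustive'`` enumerates every C(N, k) set, still reported
    under the add-one convention so the two agree as B reaches the full
    enumeration. Exhaustive mode refuses more than 500,000 sets.
    """
    n, k = int(ranked_list_length), int(set_size)
    if k < 1 or k >= n:
        raise UndefinedScoreError(f"set size {k} invalid for list length {n}")
    if method == "exhaustive":
        total = comb(n, k)
        if total > 500_000:
            raise ValueError(f"exhaustive enumeration of C({n},{k})={total} refused")
        all_hits = np.fromiter(
            (p for combo in combinations(range(1, n + 1), k) for p in combo),
            dtype=np.int64,
            count=total * k,
        ).reshape(total, k)
        null = np.sort(np.abs(es_from_hits(all_hits, n)))
    elif method == "permutation":
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        null = sample_null_abs_es(n, k, n_permutations, np.random.default_rng(seed))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(_tail_pvalues(null, abs(float(observed_es))))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1. Ties share the value
    the sorted computation produces.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = q_sorted
    return out


class PermutationNull:
    """Cache of permutation null distributions keyed by (N, set size).

    The unweighted ES null depends on the ranked list only through its
    length and the set size, so one batch of draws serves every cell that
    shares (N, k). Seeds derive from (master_seed, N, k), making batch
    scoring independent of evaluation order.
    """

    def __init__(self, master_seed: int, n_permutations: int = 10_000):
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        self.master_seed = int(master_seed)
        self.n_permutations = int(n_permutations)
        self._cache: dict[tuple[int, int], np.ndarray] = {}

    def null(self, n: int, k: int) -> np.ndarray:
        key = (int(n), int(k))
        if key not in self._cache:
            rng = rng_for(self.master_seed, "null", *key)
            self._cache[key] = sample_null_abs_es(
                key[0], key[1], self.n_permutations, rng
            )
        return self._cache[key]

    def pvalues(self, observed_es, n: int, k: int) -> np.ndarray:
        return _tail_pvalues(self.null(n, k), np.abs(np.asarray(observed_es, float)))
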