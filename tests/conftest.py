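"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (exhaustive recursion and
enumeration) and independent of the package's implementations; they are
only feasible on tiny inputs, which is exactly where they are used.
"""

from __future__ import annotations

import functools
import itertools

import numpy as np
import pytest

ALPHABET = "acgt"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=n))


def brute_levenshtein(x: str, y: str) -> int:
    """Memoized recursion over all edit scripts."""

    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
            rec(i - 1, j - 1) + (x[i - 1] != y[j - 1]),
        )

    return rec(len(x), len(y))


def brute_margin_gap(x: str, y: str, t: int) -> int:
    """Enumerate all margin decompositions with the discounted gap cost.

    Any alignment splits into: leading gaps (falling entirely on one
    string, first ``t`` free), a global alignment of the middles, and
    trailing gaps (likewise).  The minimum over all decompositions is
    the margin-gap distance.
    """
    best = None
    m, n = len(x), len(y)
    for lead_x, lead_y in itertools.chain(
        ((i, 0) for i in range(m + 1)), ((0, j) for j in range(n + 1))
    ):
        for trail_x, trail_y in itertools.chain(
            ((i, 0) for i in range(m - lead_x + 1)),
            ((0, j) for j in range(n - lead_y + 1)),
        ):
            mid_x = x[lead_x : m - trail_x]
            mid_y = y[lead_y : n - trail_y]
            cost = (
                max(0, lead_x + lead_y - t)
                + brute_levenshtein(mid_x, mid_y)
                + max(0, trail_x + trail_y - t)
            )
            if best is None or cost < best:
                best = cost
    return best


def brute_match_norm(alpha: str, beta: str, min_overlap: int, dist_fn=None):
    """Minimal post-normalized distance over the full candidate set
    suff x pref, pref x suff, sub x {beta}, {alpha} x sub; None if no
    candidate meets the length threshold.

    The enumeration is the oracle; ``dist_fn`` defaults to the brute
    recursion and may be swapped for a faster exact edit distance on
    larger strings (whose own correctness is pinned separately).
    """
    if dist_fn is None:
        dist_fn = brute_levenshtein
    la, lb = len(alpha), len(beta)
    cands = []
    for a0 in range(la):  # suffixes of alpha x prefixes of beta
        for b1 in range(1, lb + 1):
            cands.append((a0, la, 0, b1))
    for a1 in range(1, la + 1):  # prefixes of alpha x suffixes of beta
        for b0 in range(lb):
            cands.append((0, a1, b0, lb))
    for a0 in range(la):  # substrings of alpha x beta
        for a1 in range(a0 + 1, la + 1):
            cands.append((a0, a1, 0, lb))
    for b0 in range(lb):  # alpha x substrings of beta
        for b1 in range(b0 + 1, lb + 1):
            cands.append((0, la, b0, b1))
    best = None
    for a0, a1, b0, b1 in cands:
        if a1 - a0 < min_overlap or b1 - b0 < min_overlap:
            continue
        d = dist_fn(alpha[a0:a1], beta[b0:b1])
        norm = d / max(a1 - a0, b1 - b0)
        if best is None or norm < best:
            best = norm
    return best


def brute_schedule_weight(intervals_weights) -> int:
    """Max total weight over all subsets with pairwise-disjoint intervals."""
    items = list(intervals_weights)
    best = 0
    for mask in range(1 << len(items)):
        chosen = [items[i] for i in range(len(items)) if mask >> i & 1]
        ivs = sorted(iv for iv, _ in chosen)
        if any(b[0] < a[1] for a, b in zip(ivs, ivs[1:])):
            continue
        best = max(best, sum(w for _, w in chosen))
    return best
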