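"""q-gram profiles, the q-gram distance, and incremental sliding variants.

The q-gram distance (L1 distance between q-gram count vectors) lower
bounds the Levenshtein distance: ``dist(A, B) >= dist_q(A, B) / (2q)``,
because one edit creates or destroys at most ``q`` grams on each side.
It is the cheap filter used everywhere in this package to choose which
read/contig pairs deserve an exact alignment.

Profiles are sparse maps, so large ``q`` stays cheap.  The sliding
routines maintain a running count-difference and L1 norm, updating only
the grams entering and leaving each window; results are bit-identical to
recomputing every window profile from scratch.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Counter as TCounter
from collections import Counter

import numpy as np
from numba import njit

_CODE = np.full(128, -1, dtype=np.int64)
for _i, _ch in enumerate("acgtn"):
    _CODE[ord(_ch)] = _i


@dataclass(frozen=True)
class QGramProfile:
    """Sparse q-gram count vector of one string."""

    q: int
    counts: TCounter[str]
    source_length: int

    def __post_init__(self) -> None:
        expected = max(0, self.source_length - self.q + 1)
        if sum(self.counts.values()) != expected:
            raise ValueError("count total does not match source length")


def profile(s: str, q: int) -> QGramProfile:
    """Counts of every length-``q`` substring of ``s`` (empty if ``|s| < q``)."""
    if q < 1:
        raise ValueError("q must be >= 1")
    return QGramProfile(q, Counter(s[i : i + q] for i in range(len(s) - q + 1)), len(s))


def qgram_distance(p1: QGramProfile, p2: QGramProfile) -> int:
    """L1 distance between two profiles of the same ``q``."""
    if p1.q != p2.q:
        raise ValueError(f"profiles have different q: {p1.q} vs {p2.q}")
    keys = p1.counts.keys() | p2.counts.keys()
    return sum(abs(p1.counts[k] - p2.counts[k]) for k in keys)


def choose_q(overlap_length: int) -> set[int]:
    """Admissible q values for an overlap of the given length.

    q-gram profiles discriminate best for strings of length around
    ``4**q``; a value ``q`` is admissible for lengths in
    ``[4**(q-1), 4**(q+1))``.  Degenerate short overlaps (< 4) fall back
    to ``q = 2``.
    """
    if overlap_length < 1:
        raise ValueError("overlap_length must be >= 1")
    qs = set()
    q = 2
    while 4 ** (q - 1) <= overlap_length:
        if overlap_length < 4 ** (q + 1):
            qs.add(q)
        q += 1
    return qs or {2}


def normalized_qgram_score(distance: int, overlap_length: int, q: int) -> float:
    """``distance / (q * overlap_length)``: cross-q comparable surrogate for
    the post-normalized Levenshtein distance (divide by ``q`` because the
    q-gram distance over-counts each edit up to ``2q`` times)."""
    if overlap_length < 1 or q < 1:
        raise ValueError("overlap_length and q must be >= 1")
    return distance / (q * overlap_length)


def gram_codes(s: str, q: int) -> np.ndarray:
    """Integer code of every q-gram of ``s`` (base-5 over ``acgtn``)."""
    c = _CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    if np.any(c < 0):
        raise ValueError("sequence contains characters outside {a,c,g,t,n}")
    n = len(s) - q + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    g = np.zeros(n, dtype=np.int64)
    for k in range(q):
        g = g * 5 + c[k : k + n]
    return g


def sliding_read_windows(read: str, contig: str, q: int) -> np.ndarray:
    """q-gram distance between ``read`` and every same-length window of
    ``contig``; entry ``o`` is the distance at window offset ``o``.

    Maintained incrementally: moving the window one position adds the
    entering q-gram and removes the leaving one.
    """
    lr, lc = len(read), len(contig)
    if lr < q:
        raise ValueError("read shorter than q")
    if lc < lr:
        return np.empty(0, dtype=np.int64)
    win = _window_counts(contig, lr, q)  # (5**q, n_offsets)
    rvec = np.zeros(5**q, dtype=np.int64)
    np.add.at(rvec, gram_codes(read, q), 1)
    return np.abs(win - rvec[:, None]).sum(axis=0)


@functools.lru_cache(maxsize=32)
def _window_counts(contig: str, window_len: int, q: int) -> np.ndarray:
    """Gram-count prefix sums turned into per-window counts: entry
    ``[g, o]`` counts gram ``g`` in ``contig[o : o + window_len]``.
    Cached per contig because every read of a bag shares one length."""
    cg = gram_codes(contig, q)
    w = window_len - q + 1  # grams per window
    cum = np.zeros((5**q, len(cg) + 1), dtype=np.int64)
    cum[cg, np.arange(1, len(cg) + 1)] = 1
    np.cumsum(cum, axis=1, out=cum)
    return cum[:, w:] - cum[:, : len(cg) + 1 - w]


@dataclass(frozen=True)
class OverlapCandidate:
    """One equal-length overlap configuration of two contigs.

    ``shift`` is the position of beta's first symbol relative to alpha's
    first symbol; negative shifts hang beta off alpha's left end.
    """

    shift: int
    alpha_start: int
    alpha_end: int
    beta_start: int
    beta_end: int
    q: int
    distance: int

    @property
    def length(self) -> int:
        return self.alpha_end - self.alpha_start

    @property
    def score(self) -> float:
        return normalized_qgram_score(self.distance, self.length, self.q)


@njit(cache=True)
def _slide_kernel(
    alpha_g: np.ndarray, beta_g: np.ndarray, la: int, lb: int, q: int
) -> np.ndarray:  # pragma: no cover
    """q-gram distance of the two equal-length overlap windows at every
    shift (entry ``i`` is shift ``i - (lb - 1)``), maintained by adding
    the entering q-gram and removing the leaving one at each boundary."""
    size = 5**q
    diff = np.zeros(size, dtype=np.int64)
    l1 = 0
    out = np.empty(la + lb - 1, dtype=np.int64)
    s0 = -(lb - 1)
    # current boundaries of the alpha window [a0, a1) and beta window [b0, b1)
    a0, a1 = 0, min(la, s0 + lb)
    b0, b1 = lb - 1, lb
    if a1 - a0 >= q:
        for i in range(a0, a1 - q + 1):
            g = alpha_g[i]
            d = diff[g]
            l1 += abs(d + 1) - abs(d)
            diff[g] = d + 1
    if b1 - b0 >= q:
        for i in range(b0, b1 - q + 1):
            g = beta_g[i]
            d = diff[g]
            l1 += abs(d - 1) - abs(d)
            diff[g] = d - 1
    out[0] = l1
    for s in range(s0 + 1, la):
        na0 = max(0, s)
        na1 = min(la, s + lb)
        nb0 = max(0, -s)
        nb1 = min(lb, la - s)
        while a1 < na1:  # alpha window extends right: gram ending at a1+1
            a1 += 1
            if a1 - a0 >= q:
                g = alpha_g[a1 - q]
                d = diff[g]
                l1 += abs(d + 1) - abs(d)
                diff[g] = d + 1
        while a0 < na0:  # alpha window shrinks from the left
            if a1 - a0 >= q:
                g = alpha_g[a0]
                d = diff[g]
                l1 += abs(d - 1) - abs(d)
                diff[g] = d - 1
            a0 += 1
        while b0 > nb0:  # beta window extends left
            b0 -= 1
            if b1 - b0 >= q:
                g = beta_g[b0]
                d = diff[g]
                l1 += abs(d - 1) - abs(d)
                diff[g] = d - 1
        while b1 > nb1:  # beta window shrinks from the right
            if b1 - b0 >= q:
                g = beta_g[b1 - q]
                d = diff[g]
                l1 += abs(d + 1) - abs(d)
                diff[g] = d + 1
            b1 -= 1
        out[s - s0] = l1
    return out


def all_shift_distances(alpha: str, beta: str, q: int) -> np.ndarray:
    """Incremental q-gram distances for every overlap shift; entry ``i``
    corresponds to shift ``i - (len(beta) - 1)``."""
    return _slide_kernel(
        gram_codes(alpha, q), gram_codes(beta, q), len(alpha), len(beta), q
    )


def admissible_qs(min_len: int, max_len: int) -> list[int]:
    """q values whose admissible interval [4^(q-1), 4^(q+1)) meets
    [min_len, max_len]; q = 2 as degenerate fallback."""
    return [
        q
        for q in range(2, max_len.bit_length() + 2)
        if 4 ** (q - 1) <= max_len and min_len < 4 ** (q + 1)
    ] or [2]


def sliding_overlaps(alpha: str, beta: str, min_len: int) -> list[OverlapCandidate]:
    """All equal-length overlap configurations of two contigs with their
    q-gram distances, for every admissible ``q``.

    One contig slides against the other; containment positions are
    included.  Only overlaps of length >= ``min_len`` are reported.  For
    each length the q values come from :func:`choose_q`, so one shift may
    yield several candidates at different q.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    la, lb = len(alpha), len(beta)
    if min(la, lb) < min_len:
        return []
    max_len = min(la, lb)
    out: list[OverlapCandidate] = []
    for q in admissible_qs(min_len, max_len):
        lo, hi = 4 ** (q - 1), 4 ** (q + 1)
        dists = all_shift_distances(alpha, beta, q)
        for i, l1 in enumerate(dists):
            s = i - (lb - 1)
            a0, a1 = max(0, s), min(la, s + lb)
            L = a1 - a0
            if L < min_len:
                continue
            if not (lo <= L < hi or (L < 4 and q == 2)):
                continue
            out.append(OverlapCandidate(s, a0, a1, a0 - s, a1 - s, q, int(l1)))
    return out
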