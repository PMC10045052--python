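"""Edit distances: exact, banded, and the free-margin variant.

Plain Levenshtein distance is computed with edlib (Myers bit-vector,
exact).  The margin-gap variant — where up to ``t`` leading and up to
``t`` trailing gaps on either string are free — compensates for the
random placement of fixed-length reads along the genome and is a unit
cost Wagner-Fischer DP with discounted boundaries, jitted with numba.

The free-gap budget is ``t = (l/c - 1) / 2`` for read length ``l`` and
coverage ``c``: the expected offset between the closest sampled reads of
two genomes.  ``t`` is floored to an integer (a fractional free gap has
no meaning in unit-cost DP) and clamped at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from numba import njit

#: marker returned by :func:`levenshtein_banded` when the bound is exceeded
EXCEEDS = None


@dataclass(frozen=True)
class AlignmentParams:
    """Margin budget and optional band for pairwise alignment."""

    margin_t: int = 0
    band: int | None = None

    def __post_init__(self) -> None:
        if self.margin_t < 0:
            raise ValueError("margin_t must be non-negative")


def margin_budget(read_length: int, coverage: float) -> int:
    """Free margin-gap budget ``t = floor((l/c - 1) / 2)``, clamped at 0."""
    t = 0.5 * (read_length / coverage - 1.0)
    return max(0, int(np.floor(t)))


def levenshtein(x: str, y: str) -> int:
    """Unit-cost edit distance (insert / delete / substitute)."""
    if not x:
        return len(y)
    if not y:
        return len(x)
    return edlib.align(x, y, mode="NW", task="distance")["editDistance"]


def levenshtein_banded(x: str, y: str, bound: int) -> int | None:
    """Exact edit distance if it is ``<= bound``, else :data:`EXCEEDS`.

    The bound is the Ukkonen cutoff: cells that cannot lead to a result
    within the band are never computed.
    """
    if bound < 0:
        raise ValueError("bound must be non-negative")
    if not x or not y:
        d = len(x) + len(y)
        return d if d <= bound else EXCEEDS
    d = edlib.align(x, y, mode="NW", task="distance", k=bound)["editDistance"]
    return d if d >= 0 else EXCEEDS


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


@njit(cache=True)
def _margin_dp(
    x: np.ndarray, y: np.ndarray, t: int, cutoff: int
) -> int:  # pragma: no cover
    """Margin-gap DP with early abandon and a Ukkonen band.

    If every remaining exit is >= cutoff the scan aborts and returns
    cutoff (cell values are non-decreasing along DP paths, so the row
    minimum bounds all later exits).  Any path of cost < cutoff stays
    within ``|i - j| <= t + cutoff`` (deviations beyond the free margin
    cost one gap each), so cells outside that band are never computed.
    """
    m, n = x.size, y.size
    big = np.int64(1) << 40
    band = t + min(cutoff, m + n)
    prev = np.full(n + 1, big, dtype=np.int64)
    cur = np.full(n + 1, big, dtype=np.int64)
    for j in range(min(n, band) + 1):
        prev[j] = max(0, j - t)  # leading gaps in x's side, first t free
    best_exit = big
    if m == 0:
        best_exit = prev[n]
    for i in range(1, m + 1):
        jlo = max(1, i - band)
        jhi = min(n, i + band)
        if jlo > 1:
            cur[jlo - 1] = big
        cur[0] = max(0, i - t)  # leading gaps in y's side
        row_min = cur[0] if jlo == 1 else big
        for j in range(jlo, jhi + 1):
            sub = prev[j - 1] + (0 if x[i - 1] == y[j - 1] else 1)
            gap = min(prev[j], cur[j - 1]) + 1
            v = min(sub, gap)
            cur[j] = v
            if v < row_min:
                row_min = v
        if jhi < n:
            cur[jhi + 1] = big
        # trailing gaps in y's side: x[i:] unmatched
        cand = cur[n] + max(0, (m - i) - t)
        if cand < best_exit:
            best_exit = cand
        if row_min >= cutoff and best_exit >= cutoff:
            return cutoff
        prev, cur = cur, prev
    best = best_exit
    for j in range(n + 1):  # trailing gaps in x's side: y[j:] unmatched
        cand = prev[j] + max(0, (n - j) - t)
        if cand < best:
            best = cand
    return min(best, cutoff)


def margin_gap_distance(x: str, y: str, t: int) -> int:
    """Edit distance with up to ``t`` free gaps on each margin.

    On each margin (leading gaps, which fall entirely on one string, and
    trailing gaps likewise) the first ``t`` gap symbols cost 0 and any
    further margin gaps cost 1.  Internal gaps always cost 1.  With
    ``t = 0`` this is exactly :func:`levenshtein`.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if t == 0:
        return levenshtein(x, y)
    if not x or not y:
        # all gaps fall on one string and may use both margin budgets
        return max(0, len(x) + len(y) - 2 * t)
    return int(_margin_dp(_encode(x), _encode(y), t, _NO_CUTOFF))


#: effectively "no cutoff" for the bounded DP kernels
_NO_CUTOFF = 1 << 60


def margin_gap_at_most(x: str, y: str, t: int, cutoff: int) -> int:
    """Like :func:`margin_gap_distance` but may return ``cutoff`` early
    whenever the true distance is >= ``cutoff`` (exact below it)."""
    if cutoff <= 0:
        return cutoff
    if t == 0 and x and y:
        if cutoff >= _NO_CUTOFF:
            return levenshtein(x, y)
        d = levenshtein_banded(x, y, cutoff - 1)
        return d if d is not None else cutoff
    if not x or not y:
        return min(cutoff, max(0, len(x) + len(y) - 2 * t))
    return int(_margin_dp(_encode(x), _encode(y), t, cutoff))


@njit(cache=True)
def _infix_dp(
    x: np.ndarray, y: np.ndarray, t_left: int, t_right: int, cutoff: int
) -> int:  # pragma: no cover
    """Semi-global DP: y's flanks are skipped free; x may overhang y's
    left/right boundary with the first t_left/t_right overhang symbols
    free.  May abort with ``cutoff`` once no exit can be below it."""
    m, n = x.size, y.size
    prev = np.zeros(n + 1, dtype=np.int64)  # skipping y's prefix is free
    cur = np.empty(n + 1, dtype=np.int64)
    best = np.iinfo(np.int64).max
    if m == 0:
        return 0
    for i in range(1, m + 1):
        cur[0] = max(0, i - t_left)  # x's prefix overhangs y's left end
        row_min = cur[0]
        for j in range(1, n + 1):
            sub = prev[j - 1] + (0 if x[i - 1] == y[j - 1] else 1)
            gap = min(prev[j], cur[j - 1]) + 1
            v = min(sub, gap)
            cur[j] = v
            if v < row_min:
                row_min = v
        # x's suffix overhangs y's right end
        cand = cur[n] + max(0, (m - i) - t_right)
        if cand < best:
            best = cand
        if row_min >= cutoff and best >= cutoff:
            return cutoff
        prev, cur = cur, prev
    for j in range(n + 1):  # y's suffix skipped free
        if prev[j] < best:
            best = prev[j]
    return best


def infix_distance(
    x: str, y: str, t_left: int, t_right: int, cutoff: int | None = None
) -> int:
    """Best alignment of ``x`` against any region of ``y``.

    Skipping a prefix/suffix of ``y`` costs nothing (the read's location
    in the contig is arbitrary); ``x`` overhanging the left (right) end
    of ``y`` is free for the first ``t_left`` (``t_right``) symbols and
    costs 1 per symbol beyond that.  With a ``cutoff`` the value is
    exact below it and capped at it otherwise.
    """
    c = _NO_CUTOFF if cutoff is None else cutoff
    if c <= 0:
        return c
    if not x:
        return 0
    if not y:
        return min(c, max(0, len(x) - t_left - t_right))
    return int(_infix_dp(_encode(x), _encode(y), t_left, t_right, c))


@njit(cache=True)
def _min_margin_scan(
    a: np.ndarray,
    targets: np.ndarray,
    order: np.ndarray,
    dq_row: np.ndarray,
    t: int,
    two_q: int,
) -> int:  # pragma: no cover
    """Minimum margin-gap distance from ``a`` to the target rows, visited
    in the given order (increasing q-gram distance), stopping via the
    lower bound dist_rr >= dist_q / (2q) - 2t; exact-below-best DPs."""
    best = _NO_CUTOFF
    for k in range(order.size):
        idx = order[k]
        if best < _NO_CUTOFF and dq_row[idx] > two_q * (best + 2 * t):
            break
        v = _margin_dp(a, targets[idx], t, best)
        if v < best:
            best = v
            if best == 0:
                break
    return best


def min_margin_to_targets(
    a: str, target_matrix: np.ndarray, dq_row: np.ndarray, t: int, q: int
) -> int:
    """Lossless q-gram-pruned minimum margin-gap distance to a read set
    (targets pre-encoded as a byte matrix, one read per row)."""
    order = np.argsort(dq_row, kind="stable")
    return int(
        _min_margin_scan(_encode(a), target_matrix, order, dq_row, t, 2 * q)
    )


def encode_reads(reads: list[str]) -> np.ndarray:
    """Byte matrix of equal-length reads, one per row."""
    return np.frombuffer("".join(reads).encode("ascii"), dtype=np.uint8).reshape(
        len(reads), -1
    )


def post_normalized(x: str, y: str) -> float:
    """Levenshtein distance divided by the longer length; in [0, 1]."""
    if not x and not y:
        raise ValueError("post-normalized distance undefined for two empty strings")
    return levenshtein(x, y) / max(len(x), len(y))
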