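"""Read-to-contig and contig-residual-to-reads distances.

A read is matched against the most similar region of a contig: skipping
the contig's flanks around the matched region is free (the read's
location is arbitrary), and the read may overhang a *true contig end*
with the first ``t`` overhanging symbols free — the same margin budget
as in read-read matching, compensating for random read placement at the
boundaries of the assembled region.

A contig residual of length ``L`` should, at coverage ``c``, be covered
by about ``L c / l`` reads; its distance to a read bag is the sum of the
``floor(L c / l)`` smallest read-to-residual distances.
"""

from __future__ import annotations

import heapq
from math import floor

import numpy as np

from .align import _NO_CUTOFF, infix_distance, margin_budget
from .qgrams import sliding_read_windows
from .samples import ReadBag


def dist_rc(
    a: str,
    beta: str,
    t: int,
    mode: str = "fast",
    q: int = 3,
    cutoff: int | None = None,
) -> int:
    """Distance from read ``a`` to the closest matching region of contig
    ``beta``.

    ``exact`` mode runs the semi-global DP over the whole contig.
    ``fast`` mode scans window offsets in increasing sliding q-gram
    distance, runs the same DP on a window with flank ``t + d`` around
    each (``d`` = best value so far; overhang freedom is granted only at
    window boundaries that are real contig ends), and stops once the
    q-gram bound excludes any improvement: an alignment of cost ``d``
    whose span starts at offset ``i`` forces
    ``dist_q(a, window_i) <= 4 q d``.  The two boundary offsets are
    always checked (end-overhang alignments escape the interior bound),
    and if too many candidates survive the whole-contig DP is run
    instead — so the fast value always equals the exact one.

    With a ``cutoff`` the result is exact below it and capped at it
    otherwise.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if not beta:
        raise ValueError("empty contig")
    c = _NO_CUTOFF if cutoff is None else cutoff
    if c <= 0:
        return c
    if mode == "exact":
        return infix_distance(a, beta, t, t, cutoff=c)
    if mode != "fast":
        raise ValueError(f"unknown mode {mode!r}")
    la, n = len(a), len(beta)
    if n <= la + 2 * t or la < q:
        return infix_distance(a, beta, t, t, cutoff=c)
    dists = sliding_read_windows(a, beta, q)
    last = n - la

    def window_dp(o: int, flank: int, cut: int) -> int:
        w0 = max(0, o - flank)
        w1 = min(n, o + la + flank)
        return infix_distance(
            a, beta[w0:w1], t if w0 == 0 else 0, t if w1 == n else 0, cutoff=cut
        )

    # bootstrap at the minimizer offset: narrow window first, then re-check
    # with a flank wide enough (t + upper bound) to contain any better span
    o0 = int(dists.argmin())
    best = window_dp(o0, t, c)
    if 0 < best:
        best = min(best, window_dp(o0, t + best, min(best, c)))
    if best == 0:
        return 0
    cand = np.flatnonzero(dists <= 4 * q * best)
    if len(cand) > 8:  # bound not selective here; the full DP is cheaper
        return infix_distance(a, beta, t, t, cutoff=c)
    for o in sorted(set(int(o) for o in cand) | {0, last}):
        if o == o0:
            continue
        best = min(best, window_dp(o, t + best, best))
        if best == 0:
            break
    return best


def read_quota(residual_length: int, coverage: float, read_length: int) -> int:
    """Expected read count for a residual: ``floor(L c / l)``."""
    return floor(residual_length * coverage / read_length)


def dist_cR(
    alpha_res: str,
    RB: ReadBag,
    t: int | None = None,
    mode: str = "fast",
    q: int = 3,
    quota: int | None = None,
    pad_missing: bool = True,
) -> int:
    """Distance from a contig residual to the reads that should cover it.

    The ``floor(|alpha_res| c / l)`` smallest read-to-residual distances
    are summed (the optimal fixed-size subset is exactly the k smallest;
    reads already worse than the current k-th smallest are abandoned
    early, which cannot change the sum).  A zero quota contributes
    nothing.  If the bag holds fewer than the quota of reads, each
    missing read is charged the maximal per-read cost ``l`` so that
    sparse bags do not look spuriously close (``pad_missing=False``
    disables the charge).
    """
    l = RB.read_length
    if quota is None:
        if RB.coverage is None:
            raise ValueError("bag coverage is unset and no quota given")
        quota = read_quota(len(alpha_res), RB.coverage, l)
    if quota <= 0:
        return 0
    if t is None:
        t = margin_budget(l, RB.coverage)
    heap: list[int] = []  # max-heap (negated) of the k smallest so far
    for b in RB.reads:
        cut = -heap[0] if len(heap) == quota else None
        d = dist_rc(b, alpha_res, t, mode=mode, q=q, cutoff=cut)
        if len(heap) < quota:
            heapq.heappush(heap, -d)
        elif d < -heap[0]:
            heapq.heapreplace(heap, -d)
    total = -sum(heap)
    if pad_missing and len(heap) < quota:
        total += (quota - len(heap)) * l
    return total
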