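"""Read-bag distances: margin-tolerant read alignment and Monge-Elkan
aggregation, with q-gram candidate prefiltering.

Two reads sampled from homologous genome positions rarely start at the
same offset; the expected offset between the closest reads of two bags
at coverage ``c`` is ``l/c``, so up to ``t = (l/c - 1)/2`` leading and
trailing gaps are free in the read-read distance.

The Monge-Elkan distance matches every read of one bag with its closest
counterpart in the other bag and averages; it is asymmetric, lives on
the per-read scale [0, l], and is symmetrised and rescaled to
genome-length units by :func:`messg`.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .align import (
    encode_reads,
    margin_budget,
    margin_gap_distance,
    min_margin_to_targets,
)
from .qgrams import gram_codes
from .samples import ReadBag


def dist_rr(a: str, b: str, t: int) -> int:
    """Margin-tolerant distance between two reads (free margins up to ``t``)."""
    return margin_gap_distance(a, b, t)


def profile_matrix(reads: list[str], q: int) -> np.ndarray:
    """Dense q-gram count matrix, one row per read (base-5 gram codes)."""
    n = len(reads)
    mat = np.zeros((n, 5**q), dtype=np.int32)
    for i, r in enumerate(reads):
        np.add.at(mat[i], gram_codes(r, q), 1)
    return mat


def min_read_distances(
    queries: list[str],
    targets: list[str],
    t: int,
    q: int = 3,
    use_filter: bool = True,
) -> np.ndarray:
    """For every query read, the minimum :func:`dist_rr` over the targets.

    The filter is lossless: targets are visited in increasing q-gram
    distance (so the exact margin-gap DP sees the most promising, and in
    particular all minimal-q-gram-distance, candidates first) and the
    scan stops once the q-gram lower bound rules out any improvement.
    The bound combines ``dist >= dist_q / (2q)`` with the fact that
    freeing at most ``2t`` margin gaps lowers an alignment cost by at
    most ``2t``: ``dist_rr(a, b) >= dist_q(a, b) / (2q) - 2t``.  The
    result therefore always equals the exhaustive scan.
    """
    if not queries or not targets:
        raise ValueError("empty read list")
    out = np.empty(len(queries), dtype=np.int64)

    if use_filter:
        pq = cdist(
            profile_matrix(queries, q), profile_matrix(targets, q), "cityblock"
        ).astype(np.int64)
        tmat = encode_reads(targets)
        for i, a in enumerate(queries):
            out[i] = min_margin_to_targets(a, tmat, pq[i], t, q)
    else:
        for i, a in enumerate(queries):
            out[i] = min(dist_rr(a, b, t) for b in targets)
    return out


def monge_elkan(
    RA: ReadBag,
    RB: ReadBag,
    t: int | None = None,
    use_filter: bool = True,
    q: int = 3,
) -> float:
    """Mean over reads of ``RA`` of the closest margin-tolerant match in ``RB``.

    ``t`` defaults to the budget derived from ``RA``'s read length and
    coverage.  Asymmetric; range [0, l].
    """
    if len(RA) == 0 or len(RB) == 0:
        raise ValueError("Monge-Elkan distance needs two non-empty bags")
    if t is None:
        t = margin_budget(RA.read_length, RA.coverage)
    mins = min_read_distances(RA.reads, RB.reads, t, q=q, use_filter=use_filter)
    return float(mins.mean())


def messg(RA: ReadBag, RB: ReadBag, use_filter: bool = True, q: int = 3) -> float:
    """Scaled symmetric Monge-Elkan distance, in genome-length units (nt).

    Both directions are averaged (each using its own source bag's margin
    budget) and the [0, l] value is multiplied by the larger of the two
    genome-length estimates ``l |R| / c`` divided by ``l``, putting the
    result on the same scale as a Levenshtein distance between genomes.
    """
    if RA.read_length != RB.read_length:
        raise ValueError(
            f"mismatched read lengths: {RA.read_length} vs {RB.read_length}"
        )
    me_ab = monge_elkan(RA, RB, use_filter=use_filter, q=q)
    me_ba = monge_elkan(RB, RA, use_filter=use_filter, q=q)
    scale = max(RA.length_estimate, RB.length_estimate) / RA.read_length
    return 0.5 * (me_ab + me_ba) * scale
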