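"""Assembly of the four matching facets into the final genome distance.

For one direction A -> B:

1. contigs of A are matched against contigs of B (interval-scheduled),
   giving the contig-set distance ``dist_C`` and the matched length;
2. reads of each sample already assembled into that sample's own contigs
   are dropped; contig parts of A matched in step 1 are dropped, leaving
   residual segments;
3. every remaining read of A is matched to its closest read of B or
   region of a contig of B; every residual segment of A is matched to
   the reads of B that should cover it;
4. the read-level pre-measure (step 3, normalized to [0, 1]) and
   ``dist_C`` are blended with weight ``w`` = the fraction of A's
   estimated genome length covered by matched contig sequence.

The two directions are averaged and rescaled from [0, 1] to nucleotide
units by the larger estimated genome length ``l |R| / c``, so the final
value estimates the Levenshtein distance between the two genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .align import margin_budget
from .contigs import DEFAULT_MIN_OVERLAP, MatchSet, dist_C_from_matches, match_sets
from .readbag import min_read_distances
from .readcontig import dist_cR, dist_rc, read_quota
from .redundancy import filter_assembled_reads, residual_contigs
from .samples import DistanceMatrix, ReadBag, SampleTuple


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the distance pipeline (defaults follow the method)."""

    mode: str = "fast"  # contig matching / read-contig mode: "fast" or "exact"
    min_overlap: int = DEFAULT_MIN_OVERLAP
    q_read: int = 3
    use_filter: bool = True  # q-gram prefilter in read-read matching
    pad_missing_reads: bool = True


DEFAULT_CONFIG = PipelineConfig()


@dataclass(frozen=True)
class PairwiseBreakdown:
    """Per-direction diagnostics of one pairwise computation."""

    dist_C_value: float
    dist_TT_minus_R_value: float
    w: float
    dist_TT_value: float
    matched_length: int

    def __post_init__(self) -> None:
        expected = self.w * self.dist_C_value + (1 - self.w) * self.dist_TT_minus_R_value
        if abs(self.dist_TT_value - expected) > 1e-9:
            raise ValueError("inconsistent breakdown")


def dist_rT(
    a: str,
    RB_filtered: ReadBag,
    CB,
    t: int,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> int:
    """Distance from one read to the closest read or contig of a sample."""
    best = None
    if len(RB_filtered) > 0:
        best = int(
            min_read_distances(
                [a], RB_filtered.reads, t, q=config.q_read, use_filter=config.use_filter
            )[0]
        )
    for beta in CB:
        d = dist_rc(a, beta, t, mode=config.mode, q=config.q_read)
        if best is None or d < best:
            best = d
    if best is None:
        raise ValueError("target sample has neither reads nor contigs")
    return best


def contig_weight(matches: MatchSet, RA: ReadBag) -> float:
    """Weight of the contig-contig measure: matched length over the
    estimated genome length, capped at 1 (assemblies can over-report)."""
    if len(RA) == 0:
        raise ValueError("empty read bag")
    return min(
        1.0, matches.matched_alpha_length * RA.coverage / (len(RA) * RA.read_length)
    )


def _direction(
    TA: SampleTuple, TB: SampleTuple, config: PipelineConfig
) -> PairwiseBreakdown:
    """One direction of the pre-distance (Monge-Elkan style: from A to B)."""
    l = TA.read_bag.read_length
    c = TA.read_bag.coverage
    if c is None:
        raise ValueError(f"sample {TA.label!r} has no coverage")
    t = margin_budget(l, c)

    matches = match_sets(
        TA.contig_set, TB.contig_set, mode=config.mode, min_overlap=config.min_overlap
    )
    d_C = dist_C_from_matches(matches)
    w = contig_weight(matches, TA.read_bag)

    RA_f = filter_assembled_reads(TA.read_bag, TA.contig_set)
    RB_f = filter_assembled_reads(TB.read_bag, TB.contig_set)
    residuals = residual_contigs(TA.contig_set, matches)

    read_total = 0
    if len(RA_f) > 0:
        rr_mins = None
        if len(RB_f) > 0:
            rr_mins = min_read_distances(
                RA_f.reads, RB_f.reads, t, q=config.q_read, use_filter=config.use_filter
            )
        for i, a in enumerate(RA_f.reads):
            best = None if rr_mins is None else int(rr_mins[i])
            for beta in TB.contig_set:
                if best == 0:
                    break
                d = dist_rc(
                    a, beta, t, mode=config.mode, q=config.q_read, cutoff=best
                )
                if best is None or d < best:
                    best = d
            if best is None:
                raise ValueError(
                    f"sample {TB.label!r} has neither reads nor contigs to match against"
                )
            read_total += best

    quota_total = 0
    residual_total = 0
    for seg in residuals:
        quota = read_quota(len(seg), c, l)
        if quota == 0:
            continue
        quota_total += quota
        if len(RB_f) > 0:
            residual_total += dist_cR(
                seg.seq,
                RB_f,
                t=t,
                mode=config.mode,
                q=config.q_read,
                quota=quota,
                pad_missing=config.pad_missing_reads,
            )
        elif config.pad_missing_reads:
            residual_total += quota * l

    denominator = l * (len(RA_f) + quota_total)
    if denominator == 0:
        d_ttr = 0.0  # nothing left to compare after redundancy filtering
    else:
        d_ttr = (read_total + residual_total) / denominator
    d_tt = w * d_C + (1 - w) * d_ttr
    return PairwiseBreakdown(d_C, d_ttr, w, d_tt, matches.matched_alpha_length)


def dist_TT(
    TA: SampleTuple, TB: SampleTuple, config: PipelineConfig = DEFAULT_CONFIG
) -> PairwiseBreakdown:
    """Directional pre-distance in [0, 1] with its diagnostics."""
    return _direction(TA, TB, config)


def final_distance(
    TA: SampleTuple,
    TB: SampleTuple,
    config: PipelineConfig = DEFAULT_CONFIG,
    with_breakdown: bool = False,
):
    """Symmetric genome distance estimate in nucleotide units.

    Both directional pre-distances are averaged and multiplied by the
    larger estimated genome length; with equal read length and coverage
    this is ``l max(|R_A|, |R_B|) / c``.
    """
    for T in (TA, TB):
        if len(T.read_bag) == 0 or T.read_bag.coverage is None:
            raise ValueError(
                f"sample {T.label!r} needs a non-empty read bag with coverage "
                "(the genome-length scale is estimated from it)"
            )
    ab = _direction(TA, TB, config)
    ba = _direction(TB, TA, config)
    scale = max(TA.read_bag.length_estimate, TB.read_bag.length_estimate)
    value = 0.5 * (ab.dist_TT_value + ba.dist_TT_value) * scale
    if with_breakdown:
        return value, {"ab": ab, "ba": ba, "scale": scale}
    return value


def distance_matrix(
    samples: list[SampleTuple],
    config: PipelineConfig = DEFAULT_CONFIG,
    with_breakdown: bool = False,
):
    """All-pairs symmetric distance matrix over the samples."""
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    labels = [s.label for s in samples]
    n = len(samples)
    values = np.zeros((n, n))
    report: dict[str, dict] = {}
    for i, j in combinations(range(n), 2):
        if with_breakdown:
            d, br = final_distance(samples[i], samples[j], config, with_breakdown=True)
            report[f"{labels[i]}|{labels[j]}"] = br
        else:
            d = final_distance(samples[i], samples[j], config)
        values[i, j] = values[j, i] = d
    matrix = DistanceMatrix(labels, values)
    if with_breakdown:
        return matrix, report
    return matrix
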