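"""Removal of duplicate information before cross-type matching.

Reads that were assembled into a contig of their own sample carry no
extra information and are dropped before read-level matching.  Likewise,
once parts of a contig are matched against the opposite contig set, only
the unmatched residual segments are compared against the opposite reads.
"""

from __future__ import annotations

from dataclasses import dataclass

from .contigs import MatchSet
from .samples import ContigSet, ReadBag


def filter_assembled_reads(RA: ReadBag, CA: ContigSet) -> ReadBag:
    """Reads of ``RA`` that are not exact substrings of any contig of ``CA``.

    Multi-pattern exact matching over fixed-length reads: membership in
    the set of all read-length substrings of the contigs, built in one
    linear pass per contig.  Read length and coverage carry over.
    """
    if len(CA) == 0 or len(RA) == 0:
        return ReadBag(list(RA.reads), RA.read_length, RA.coverage)
    l = RA.read_length
    lmers: set[str] = set()
    for contig in CA:
        for i in range(len(contig) - l + 1):
            lmers.add(contig[i : i + l])
    kept = [r for r in RA.reads if r not in lmers]
    return ReadBag(kept, l, RA.coverage)


@dataclass(frozen=True)
class ResidualSegment:
    """An unmatched stretch of one contig."""

    contig_index: int
    start: int
    end: int
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


def residual_contigs(CA: ContigSet, matches: MatchSet) -> list[ResidualSegment]:
    """Unmatched segments of every contig of ``CA``.

    For each contig, the matched alpha intervals (disjoint by the match
    set invariant) are removed and the complementary segments returned;
    empty segments are dropped.  Interleaving residuals with matched
    intervals reconstructs each contig exactly.
    """
    by_alpha: dict[int, list[tuple[int, int]]] = {}
    for p in matches:
        by_alpha.setdefault(p.alpha_id, []).append(p.alpha_interval)
    out: list[ResidualSegment] = []
    for i, contig in enumerate(CA):
        ivs = sorted(by_alpha.get(i, []))
        for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping matched intervals on contig {i}")
        pos = 0
        for s, e in ivs:
            if s > pos:
                out.append(ResidualSegment(i, pos, s, contig[pos:s]))
            pos = e
        if pos < len(contig):
            out.append(ResidualSegment(i, pos, len(contig), contig[pos:]))
    return out
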