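"""Domain types and sequence I/O.

Sequences are DNA strings over the lowercase alphabet ``{a, c, g, t}``
(uppercase input is folded).  A *sample* bundles what sequencing plus a
partial assembly delivers for one organism: a bag of fixed-length reads
and an optional set of contigs.  All coordinates in the package are
0-based, half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TSequence

import numpy as np
from Bio import SeqIO

ALPHABET = frozenset("acgt")
#: contigs may retain ``n`` as a fifth symbol that mismatches every base
CONTIG_ALPHABET = frozenset("acgtn")


class ParseError(ValueError):
    """Raised for malformed FASTA/FASTQ/PHYLIP input."""


@dataclass(frozen=True)
class Sequence:
    """A labelled DNA string."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadBag:
    """A bag of constant-length reads with fold coverage ``c``.

    The bag keeps duplicates: reads are sampled i.i.d. with replacement,
    so two identical reads are two independent observations.
    """

    reads: list[str]
    read_length: int
    coverage: float | None = None

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read length must be positive")
        for r in self.reads:
            if len(r) != self.read_length:
                raise ValueError(
                    f"read of length {len(r)} in a bag of read length {self.read_length}"
                )
        if self.coverage is not None and self.coverage <= 0:
            raise ValueError("coverage must be positive")

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def length_estimate(self) -> float:
        """Estimated source-genome length ``l * |R| / c``."""
        if self.coverage is None:
            raise ValueError("coverage is unset")
        return self.read_length * len(self.reads) / self.coverage


@dataclass
class ContigSet:
    """Assembled contigs: putative non-overlapping substrings of the genome."""

    contigs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.contigs:
            if not s:
                raise ValueError("empty contig")

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self):
        return iter(self.contigs)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs)


@dataclass
class SampleTuple:
    """One sample: read bag plus (possibly empty) contig set."""

    label: str
    read_bag: ReadBag
    contig_set: ContigSet = field(default_factory=ContigSet)

    def __post_init__(self) -> None:
        if len(self.read_bag) == 0 and len(self.contig_set) == 0:
            raise ValueError(f"sample {self.label!r} has neither reads nor contigs")


class DistanceMatrix:
    """Symmetric matrix of pairwise distances with sample labels.

    Symmetry and a zero diagonal are asserted on construction so every
    matrix the pipeline emits is a valid dissimilarity matrix.
    """

    def __init__(self, labels: TSequence[str], values: np.ndarray) -> None:
        labels = list(labels)
        values = np.asarray(values, dtype=float)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels")
        if values.shape != (len(labels), len(labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(values, values.T, rtol=0, atol=1e-9):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0):
            raise ValueError("diagonal is not zero")
        if np.any(values < -1e-12):
            raise ValueError("negative distances")
        self.labels = labels
        self.values = values

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        """Strictly-upper-triangle entries, row-major (scipy ordering)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


def _normalize(seq: str, *, allow_n: bool) -> str:
    s = seq.lower()
    allowed = CONTIG_ALPHABET if allow_n else ALPHABET
    bad = set(s) - allowed
    if bad:
        raise ParseError(f"invalid characters {sorted(bad)} in sequence")
    return s


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a FASTA file into lowercase :class:`Sequence` records.

    Characters outside ``{a,c,g,t,n}`` (after case folding) are rejected.
    """
    path = Path(path)
    records = []
    with open(path) as handle:
        first = handle.readline()
        if not first.startswith(">"):
            raise ParseError(f"{path}:1: expected FASTA header, got {first[:30]!r}")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            records.append(Sequence(rec.id, _normalize(str(rec.seq), allow_n=True)))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[Sequence], path: str | Path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.seq}\n")


def read_fastq(path: str | Path, drop_ambiguous: bool = True) -> ReadBag:
    """Read a FASTQ file into a :class:`ReadBag` (coverage unset).

    Quality strings are discarded.  Reads containing ``n`` are dropped by
    default (they violate the model of reads as exact genome substrings).
    All retained reads must share one length.
    """
    reads: list[str] = []
    length: int | None = None
    for rec in SeqIO.parse(str(path), "fastq"):
        s = _normalize(str(rec.seq), allow_n=True)
        if "n" in s:
            if drop_ambiguous:
                continue
            raise ParseError(f"ambiguous base in read {rec.id!r}")
        if length is None:
            length = len(s)
        elif len(s) != length:
            raise ParseError(
                f"{path}: mixed read lengths {length} and {len(s)} (read {rec.id!r})"
            )
        reads.append(s)
    if length is None:
        raise ParseError(f"{path}: no usable reads")
    return ReadBag(reads, length)


def write_fastq(bag: ReadBag, path: str | Path, prefix: str = "read") -> None:
    qual = "I" * bag.read_length
    with open(path, "w") as handle:
        for i, r in enumerate(bag.reads):
            handle.write(f"@{prefix}{i}\n{r}\n+\n{qual}\n")


def load_sample(
    label: str,
    reads_path: str | Path,
    contigs_path: str | Path | None = None,
    coverage: float | None = None,
) -> SampleTuple:
    """Load one sample from disk and resolve its coverage.

    If ``coverage`` is not supplied it is estimated by inverting
    ``c = l |R| / |A|`` with the total contig length standing in for the
    unknown genome length ``|A|``.  Without contigs the coverage must be
    given explicitly.
    """
    bag = read_fastq(reads_path)
    contig_set = ContigSet()
    if contigs_path is not None:
        contig_set = ContigSet([rec.seq for rec in read_fasta(contigs_path)])
    if coverage is not None:
        bag.coverage = coverage
    else:
        if len(contig_set) == 0:
            raise ValueError(
                f"sample {label!r}: coverage not given and no contigs to estimate it from"
            )
        bag.coverage = bag.read_length * len(bag) / contig_set.total_length
    return SampleTuple(label, bag, contig_set)


def write_phylip(matrix: DistanceMatrix, path: str | Path) -> None:
    """Write a square PHYLIP distance matrix (relaxed label width)."""
    with open(path, "w") as handle:
        handle.write(f"{len(matrix.labels)}\n")
        for label, row in zip(matrix.labels, matrix.values):
            cells = " ".join(f"{v:.6f}" for v in row)
            handle.write(f"{label}  {cells}\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    with open(path) as handle:
        lines = [ln for ln in handle.read().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except ValueError as exc:
        raise ParseError(f"{path}:1: expected taxon count") from exc
    if len(lines) != n + 1:
        raise ParseError(f"{path}: expected {n} rows, found {len(lines) - 1}")
    labels, rows = [], []
    for ln in lines[1:]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(labels, np.array(rows))
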