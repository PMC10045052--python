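"""Synthetic data generation for controlled experiments.

The generator realises the data model the estimator assumes: genomes
are i.i.d. uniform DNA strings; related genomes differ by a given number
of point mutations (substitutions, insertions, deletions); reads are
exact fixed-length substrings sampled i.i.d. with replacement uniformly
over all start positions at a chosen fold coverage; contigs are
non-overlapping true substrings covering a chosen fraction of the
genome.  Everything is deterministic given a seed.

What this does not emulate: sequencing errors, GC or positional
coverage bias, mis-assembled (chimeric) contigs — so results on this
data bound what the method can do, not what noisy real data yields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .align import levenshtein
from .samples import (
    ContigSet,
    DistanceMatrix,
    ReadBag,
    SampleTuple,
    Sequence,
    read_fasta,
    read_fastq,
    read_phylip,
    write_fasta,
    write_fastq,
    write_phylip,
)

_BASES = np.array(list("acgt"))

#: default mutation-type proportions: substitutions dominate because the
#: target quantity is the number of point mutations between genomes
DEFAULT_WEIGHTS = (0.8, 0.1, 0.1)  # substitution, insertion, deletion


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_genome(n: int, seed) -> Sequence:
    """I.i.d. uniform DNA string of length ``n``."""
    if n < 1:
        raise ValueError("genome length must be >= 1")
    rng = _rng(seed)
    return Sequence(f"genome_{n}", "".join(rng.choice(_BASES, size=n)))


def mutate(
    A: Sequence,
    m: int,
    seed,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> Sequence:
    """Apply ``m`` point edits at uniformly random positions.

    Each edit is a substitution (to a different base), an insertion, or
    a deletion, drawn with the given proportions.  By construction the
    Levenshtein distance to the source is at most ``m`` (edits may
    cancel).  Deleting from an empty string is re-sampled as insertion.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    rng = _rng(seed)
    p = np.asarray(weights, dtype=float)
    p = p / p.sum()
    s = list(A.seq)
    for _ in range(m):
        op = rng.choice(3, p=p)
        if op == 2 and not s:
            op = 1
        if op == 0 and not s:
            op = 1
        if op == 0:  # substitution
            i = int(rng.integers(len(s)))
            others = [b for b in "acgt" if b != s[i]]
            s[i] = others[int(rng.integers(3))]
        elif op == 1:  # insertion
            i = int(rng.integers(len(s) + 1))
            s.insert(i, "acgt"[int(rng.integers(4))])
        else:  # deletion
            i = int(rng.integers(len(s)))
            del s[i]
    return Sequence(f"{A.id}_m{m}", "".join(s))


def sample_reads(A: Sequence, l: int, c: float, seed) -> ReadBag:
    """Sample ``round(c |A| / l)`` reads of length ``l`` uniformly i.i.d.
    with replacement over all start positions."""
    n = len(A.seq)
    if n < l:
        raise ValueError(f"genome of length {n} shorter than read length {l}")
    rng = _rng(seed)
    count = int(round(c * n / l))
    starts = rng.integers(0, n - l + 1, size=count)
    return ReadBag([A.seq[s : s + l] for s in starts], l, c)


def sample_contigs(
    A: Sequence,
    fraction: float,
    min_len: int,
    max_len: int,
    seed,
) -> ContigSet:
    """Non-overlapping true substrings totalling about ``fraction |A|``.

    Contig lengths are uniform in ``[min_len, max_len]``; gaps between
    placed contigs are multinomially random.  Contigs are returned in
    random order so their genome positions do not leak.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if not 1 <= min_len <= max_len:
        raise ValueError("need 1 <= min_len <= max_len")
    n = len(A.seq)
    rng = _rng(seed)
    target = fraction * n
    if fraction == 0:
        return ContigSet()
    if target < min_len:
        warnings.warn(
            f"target contig total {target:.0f} nt below min_len {min_len}; "
            "returning no contigs"
        )
        return ContigSet()
    lengths: list[int] = []
    total = 0
    while total < target:
        L = int(rng.integers(min_len, max_len + 1))
        if total + L > n:
            L = n - total
            if L < min_len:
                break
        lengths.append(L)
        total += L
    k = len(lengths)
    gaps = rng.multinomial(n - total, np.full(k + 1, 1.0 / (k + 1)))
    contigs = []
    pos = 0
    for g, L in zip(gaps, lengths):
        pos += int(g)
        contigs.append(A.seq[pos : pos + L])
        pos += L
    order = rng.permutation(k)
    return ContigSet([contigs[i] for i in order])


@dataclass
class Dataset:
    """A simulated cohort with its ground truth."""

    samples: list[SampleTuple]
    genomes: list[Sequence]
    reference: DistanceMatrix
    true_tree_newick: str
    params: dict


def _random_tree_genomes(
    n_samples: int,
    genome_len: int,
    mutations: tuple[int, int],
    rng: np.random.Generator,
    weights: tuple[float, float, float],
) -> tuple[list[Sequence], str]:
    """Evolve genomes along a random binary tree; returns leaf genomes and
    the generating topology as Newick with edge lengths = mutation counts."""
    root = random_genome(genome_len, rng)
    # random bifurcating shape: repeatedly join two random lineages
    shapes = [(f"s{i + 1}", f"s{i + 1}") for i in range(n_samples)]  # (newick, key)
    while len(shapes) > 1:
        i, j = sorted(rng.choice(len(shapes), size=2, replace=False))
        a, b = shapes[i], shapes[j]
        mi = int(rng.integers(mutations[0], mutations[1] + 1))
        mj = int(rng.integers(mutations[0], mutations[1] + 1))
        merged = (f"({a[0]}:{mi},{b[0]}:{mj})", (a[1], mi, b[1], mj))
        shapes = [s for k, s in enumerate(shapes) if k not in (i, j)] + [merged]
    newick = shapes[0][0] + ";"

    genomes: dict[str, Sequence] = {}

    def grow(key, genome: Sequence) -> None:
        if isinstance(key, str):
            genomes[key] = Sequence(key, genome.seq)
            return
        left, mi, right, mj = key
        grow(left, mutate(genome, mi, rng, weights))
        grow(right, mutate(genome, mj, rng, weights))

    grow(shapes[0][1], root)
    labels = [f"s{i + 1}" for i in range(n_samples)]
    return [genomes[lb] for lb in labels], newick


def make_dataset(
    n_samples: int = 8,
    genome_len: int = 5000,
    mutations: tuple[int, int] = (50, 400),
    l: int = 100,
    c: float = 5.0,
    contig_fraction: float = 0.6,
    contig_min_len: int = 200,
    contig_max_len: int = 800,
    seed: int = 0,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> Dataset:
    """Simulate a cohort of related genomes with reads and contigs.

    Genomes evolve along a random binary tree with a uniform number of
    point mutations per edge; the reference matrix holds the exact
    pairwise Levenshtein distances of the true genomes.
    """
    if n_samples < 2:
        raise ValueError("need at least two samples")
    rng = _rng(seed)
    genomes, newick = _random_tree_genomes(
        n_samples, genome_len, mutations, rng, weights
    )
    samples = []
    for g in genomes:
        bag = sample_reads(g, l, c, rng)
        contigs = sample_contigs(g, contig_fraction, contig_min_len, contig_max_len, rng)
        samples.append(SampleTuple(g.id, bag, contigs))
    n = len(genomes)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = levenshtein(genomes[i].seq, genomes[j].seq)
    reference = DistanceMatrix([g.id for g in genomes], values)
    params = dict(
        n_samples=n_samples,
        genome_len=genome_len,
        mutations=list(mutations),
        l=l,
        c=c,
        contig_fraction=contig_fraction,
        contig_min_len=contig_min_len,
        contig_max_len=contig_max_len,
        seed=seed if isinstance(seed, int) else None,
        weights=list(weights),
    )
    return Dataset(samples, genomes, reference, newick, params)


def write_dataset(dataset: Dataset, directory: str | Path) -> None:
    """Write a dataset as plain FASTQ/FASTA/PHYLIP files plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"params": dataset.params, "samples": []}
    for sample in dataset.samples:
        reads_file = f"{sample.label}.fastq"
        write_fastq(sample.read_bag, directory / reads_file, prefix=f"{sample.label}_r")
        entry = {
            "label": sample.label,
            "reads": reads_file,
            "coverage": float(sample.read_bag.coverage),
        }
        if len(sample.contig_set) > 0:
            contig_file = f"{sample.label}_contigs.fasta"
            write_fasta(
                [
                    Sequence(f"{sample.label}_c{i}", s)
                    for i, s in enumerate(sample.contig_set)
                ],
                directory / contig_file,
            )
            entry["contigs"] = contig_file
        manifest["samples"].append(entry)
    write_fasta(dataset.genomes, directory / "genomes.fasta")
    write_phylip(dataset.reference, directory / "reference.phylip")
    (directory / "true_tree.nwk").write_text(dataset.true_tree_newick + "\n")
    manifest["genomes"] = "genomes.fasta"
    manifest["reference"] = "reference.phylip"
    manifest["true_tree"] = "true_tree.nwk"
    with open(directory / "manifest.yaml", "w") as handle:
        yaml.safe_dump(manifest, handle, sort_keys=True)


def load_dataset(directory: str | Path) -> Dataset:
    """Load a dataset directory written by :func:`write_dataset`."""
    directory = Path(directory)
    with open(directory / "manifest.yaml") as handle:
        manifest = yaml.safe_load(handle)
    samples = []
    for entry in manifest["samples"]:
        bag = read_fastq(directory / entry["reads"])
        bag.coverage = entry["coverage"]
        contigs = ContigSet()
        if "contigs" in entry:
            contigs = ContigSet(
                [rec.seq for rec in read_fasta(directory / entry["contigs"])]
            )
        samples.append(SampleTuple(entry["label"], bag, contigs))
    genomes = read_fasta(directory / manifest["genomes"])
    reference = read_phylip(directory / manifest["reference"])
    newick = (directory / manifest["true_tree"]).read_text().strip()
    return Dataset(samples, genomes, reference, newick, manifest["params"])
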