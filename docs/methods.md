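# Methods

This note documents the model behind `pasdist`, the parameters that
matter, the numerical conventions, and what the synthetic benchmarks do
and do not demonstrate.

## Data model and assumptions

A sample is a tuple `T_A = (R_A, C_A)`: a bag of reads of one constant
length `l` (duplicates kept — sampling is with replacement) and an
optional set of contigs.  The model assumes

* reads are exact substrings of the genome, sampled i.i.d. uniformly
  over start positions at fold coverage `c = l·|R_A|/|A|`;
* contigs are substrings of the genome, pairwise non-overlapping in it;
* sequences are compared as given — no reverse-complement search.

Coverage may be supplied per sample or estimated by inverting the
coverage identity with the total contig length standing in for the
unknown genome length.  All coordinates are 0-based, half-open.
Sequences are lowercased internally; reads containing `n` are dropped
(they violate the exact-substring model), contigs keep `n` as a fifth
symbol that mismatches everything (contigs are long and dropping them
loses too much signal).

## Distance construction

**Margin-tolerant read distance.**  Two reads drawn from homologous
positions are offset by a random shift; at coverage `c` the expected
offset to the nearest read is `l/c`, so the first
`t = ⌊(l/c − 1)/2⌋` leading and trailing gaps are free (each margin has
its own budget; gaps beyond it cost 1, as do internal gaps).  `t` is
floored — a fractional free gap has no meaning in unit-cost DP — and
clamped at 0 when `c > l`.

**Read–contig distance.**  A read is aligned semi-globally: skipping
contig flanks around the matched region is free, and overhanging a
*true contig end* is free up to `t`.  Free overhangs apply only at real
contig ends, not at arbitrary windows — otherwise read tails could be
trimmed for free in the middle of a contig, and the windowed fast path
could never reproduce the exhaustive value.

**Contig–contig matching.**  Candidates are suffix–prefix overlaps and
containments with both lengths ≥ `min_overlap` (default 20 nt, which
suppresses random micro-overlaps); the minimised objective is the
post-normalized edit distance.  Per source contig, candidate matches
against the whole opposite set are reconciled by weighted interval
scheduling with weight `max(|α*|, |β*|) − edit` (the amount of agreeing
sequence a match contributes).  Matches with normalized distance
≥ 0.45 are discarded before scheduling: the best overlap-optimized
normalized edit distance between *unrelated* random DNA concentrates
just above 0.46 (measured on a 60-pair null sample), so such matches
carry no homology signal yet would otherwise always be scheduled
(their weight is positive) and inflate the contig distance.  Setting
`max_norm=None` restores the unfiltered behaviour.

**Combination.**  Reads assembled into their own sample's contigs are
removed (exact substring test over the contig `l`-mer set — equivalent
to a multi-pattern automaton pass for fixed-length patterns).  Contig
stretches unmatched after scheduling become residual segments; each is
charged the sum of the `⌊L·c/l⌋` smallest read distances (if the bag
cannot supply that many reads, missing reads cost `l` each so sparse
bags do not look spuriously close).  The read-level facets are
normalized to `[0, 1]` by `l·(|R_A'| + Σ quotas)`; an empty denominator
yields 0 (nothing left to compare).  The contig distance of an empty
match set is 1, but its weight `w = min(1, |match|·c/(|R_A|·l))` is
then 0, so the convention is inert.  The two directional pre-distances
are averaged and rescaled by the larger estimated genome length
`l·|R|/c`.  When the two bags disagree in `l` or `c`, each direction
uses its source bag's parameters and the scale uses the larger length
estimate; with shared parameters this reduces to the usual
`l·max(|R_A|, |R_B|)/c`.

## q-gram acceleration (lossless)

The q-gram distance (L1 between count profiles) obeys
`dist(A,B) ≥ dist_q(A,B)/(2q)`.  All fast paths use it only to *prune*:

* read–read: targets are scanned in increasing q-gram distance and the
  scan stops once `dist_q/(2q) − 2t` exceeds the best exact value
  (freeing ≤ 2t margin gaps lowers any alignment cost by at most 2t);
* read–contig: window offsets are scanned in increasing sliding q-gram
  distance; an alignment of cost `d` starting at offset `i` forces
  `dist_q(read, window_i) ≤ 4qd`, the DP window gets flank `t + d`,
  contig-boundary offsets are always checked, and if the bound is not
  selective the whole-contig DP (which is cheap) runs instead;
* contig–contig: equal-length overlap configurations are enumerated by
  a sliding scan that updates the entering/leaving grams, with `q`
  admissible for overlap length `L` when `4^(q−1) ≤ L < 4^(q+1)`
  (below length 4, `q = 2` is used).  Profiles saturate towards the
  upper end of each interval, so scores are ranked *within* each
  admissible `q` (normalized as `dist_q/(qL)` per the lower bound) and
  the shortlisted candidates from all `q` are re-scored with the exact
  banded edit distance, which adjudicates across `q`.

Consequently fast mode equals exhaustive computation exactly — this is
asserted by tests over hundreds of randomized instances, including
unrelated read/contig pairs.

Exact edit distances use edlib (Myers bit-vector); the banded variant
doubles the Ukkonen cutoff from the q-gram lower bound until it
succeeds.  The margin and semi-global DPs are unit-cost Wagner-Fischer
variants with discounted boundaries, run inside numba kernels with two
exact speed-ups: early abandon once no remaining exit can beat the
caller's current best (cell values are non-decreasing along DP paths)
and a Ukkonen band of half-width `t + cutoff` (a path deviating further
must spend more than `cutoff` on gaps).

## Tree building and evaluation

Distance matrices (symmetric, zero-diagonal — asserted on
construction) are written as square PHYLIP.  Neighbor joining is
delegated to scikit-bio and is exact on additive matrices; negative
branch lengths are clamped to 0 on output and for rooting, raw values
kept internally.  For comparisons: Pearson correlation over
strictly-upper-triangle entries (undefined — NaN — when either matrix
is constant); the Fowlkes-Mallows index
`B_k = TP/√((TP+FP)(TP+FN))` after midpoint-rooting and cutting each
tree to `k` clusters by repeatedly splitting the cluster whose root has
the greatest leaf-height (all-singleton versus all-singleton degenerates
to agreement, `B_n = 1`); and the triplet distance, counting 3-leaf
subsets whose midpoint-rooted induced topologies differ (an unresolved
triplet agrees only with an unresolved one).

## Synthetic data

The generator realises the model exactly: uniform random genomes,
point-mutation evolution (default 80 % substitutions, 10 % insertions,
10 % deletions — substitutions dominate because the target quantity is
the point-mutation count), uniform i.i.d. read sampling over all
`|A| − l + 1` start positions with `round(c|A|/l)` reads, and
non-overlapping true-substring contigs of uniform random length in
`[min_len, max_len]` placed with multinomial gaps and returned shuffled.
Cohorts evolve along a random bifurcating tree with a uniform number of
mutations per edge; the reference matrix holds exact pairwise
Levenshtein distances of the true genomes.

It does **not** emulate sequencing errors, coverage bias, or chimeric
mis-assemblies.  Passing benchmarks therefore show that the estimator
recovers distances when its model holds; on real data, assembly errors
and read noise will degrade the contig weight and add a noise floor.

## Benchmark conditions

The end-to-end checks use cohorts of 8 genomes of 5 kb evolved with
50–400 mutations per edge, reads of l = 100 at c = 5, contigs covering
60 % of each genome (lengths 200–800 nt), across 5 fixed seeds — sizes
at which exact reference distances are computable and a full run
finishes in minutes on one CPU.  Observed there: Pearson ≥ 0.98 versus
the exact reference with contigs, ≥ 0.99 with reads only (reads at
c = 5 carry the whole genome; contigs add speed and interpretability
more than accuracy on clean data), NJ topology recovered on 4–5 of 5
seeds (misses occur on trees with very short internal edges), and a
0–500 mutation ladder tracked with Spearman ≥ 0.95.  The estimate
carries a positive bias (margin charging and selection noise) that is
approximately proportional across pairs, so correlations and
topologies are preserved even where absolute distances overshoot.

## Known limitations

* No reverse-complement handling; inputs must be consistently stranded.
* Exact contig matching mode is quadratic per contig pair and intended
  for validation at small scale; fast mode is the default everywhere.
* `B_k` values depend on the rooting/cut convention above; other
  conventions give different absolute values.
* Heterogeneous `l`/`c` across samples is supported but the scale
  generalization (larger length estimate) is a declared choice, not a
  property of the underlying formulation.
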