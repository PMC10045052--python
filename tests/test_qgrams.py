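"""q-gram profiles, distances, and the incremental sliding machinery."""

import numpy as np
import pytest

from conftest import random_dna
from pasdist.align import levenshtein
from pasdist.qgrams import (
    choose_q,
    normalized_qgram_score,
    profile,
    qgram_distance,
    sliding_overlaps,
    sliding_read_windows,
)


class TestProfile:
    @pytest.mark.parametrize(
        "s, q, expected",
        [
            ("acgt", 2, {"ac": 1, "cg": 1, "gt": 1}),
            ("aaaa", 2, {"aa": 3}),
            ("ac", 3, {}),
        ],
    )
    def test_examples(self, s, q, expected):
        assert dict(profile(s, q).counts) == expected

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError):
            profile("acgt", 0)

    def test_count_total_invariant(self, rng):
        for _ in range(30):
            s = random_dna(rng, int(rng.integers(0, 30)))
            q = int(rng.integers(1, 6))
            p = profile(s, q)
            assert sum(p.counts.values()) == max(0, len(s) - q + 1)


class TestQgramDistance:
    def test_examples(self):
        assert qgram_distance(profile("acca", 2), profile("acga", 2)) == 4
        assert qgram_distance(profile("acg", 2), profile("", 2)) == 2
        p = profile("acgtacgt", 3)
        assert qgram_distance(p, p) == 0

    def test_mismatched_q_rejected(self):
        with pytest.raises(ValueError):
            qgram_distance(profile("acgt", 2), profile("acgt", 3))

    def test_pseudometric(self, rng):
        strings = [random_dna(rng, int(rng.integers(3, 15))) for _ in range(12)]
        profs = [profile(s, 2) for s in strings]
        for p1 in profs:
            for p2 in profs:
                assert qgram_distance(p1, p2) == qgram_distance(p2, p1)
                for p3 in profs:
                    assert qgram_distance(p1, p2) <= qgram_distance(
                        p1, p3
                    ) + qgram_distance(p3, p2)

    def test_distinct_strings_can_collide(self):
        # rotations share all internal grams: a genuine pseudometric zero
        assert qgram_distance(profile("cacac", 2), profile("acaca", 2)) == 0


class TestChooseQ:
    @pytest.mark.parametrize(
        "length, expected",
        [(256, {4, 5}), (20, {2, 3}), (1, {2}), (4, {2}), (16, {2, 3})],
    )
    def test_examples(self, length, expected):
        assert choose_q(length) == expected

    def test_lower_bound_is_two(self, rng):
        for L in rng.integers(1, 5000, size=50):
            qs = choose_q(int(L))
            assert qs and min(qs) >= 2


class TestNormalizedScore:
    def test_examples(self):
        assert normalized_qgram_score(0, 100, 4) == 0.0
        assert normalized_qgram_score(8, 64, 4) == pytest.approx(0.03125)

    def test_halving_q_doubles_score(self):
        assert normalized_qgram_score(6, 50, 2) == pytest.approx(
            2 * normalized_qgram_score(6, 50, 4)
        )


class TestEditDistanceBound:
    def test_qgram_distance_lower_bounds_levenshtein(self, rng):
        """dist(A, B) >= dist_q(A, B) / (2q) on random pairs."""
        for _ in range(200):
            a = random_dna(rng, int(rng.integers(10, 120)))
            b = random_dna(rng, int(rng.integers(10, 120)))
            lev = levenshtein(a, b)
            for q in (2, 3, 4):
                dq = qgram_distance(profile(a, q), profile(b, q))
                assert lev >= dq / (2 * q)


class TestSlidingReadWindows:
    def test_exact_occurrence_scores_zero(self, rng):
        contig = random_dna(rng, 80)
        read = contig[30:50]
        dists = sliding_read_windows(read, contig, 3)
        assert dists[30] == 0

    def test_equal_lengths_single_offset(self, rng):
        s = random_dna(rng, 25)
        assert len(sliding_read_windows(s, s, 3)) == 1

    def test_matches_from_scratch_recomputation(self, rng):
        for _ in range(40):
            contig = random_dna(rng, int(rng.integers(10, 64)))
            read = random_dna(rng, int(rng.integers(4, len(contig) + 1)))
            q = int(rng.integers(2, 5))
            if len(read) < q:
                continue
            dists = sliding_read_windows(read, contig, q)
            pr = profile(read, q)
            for o, d in enumerate(dists):
                window = contig[o : o + len(read)]
                assert d == qgram_distance(pr, profile(window, q))


class TestSlidingOverlaps:
    def test_identical_contigs_include_zero_full_overlap(self, rng):
        s = random_dna(rng, 40)
        full = [c for c in sliding_overlaps(s, s, 4) if c.length == 40]
        assert full and all(c.distance == 0 for c in full)

    def test_too_short_contigs_yield_nothing(self, rng):
        assert sliding_overlaps(random_dna(rng, 5), random_dna(rng, 8), 10) == []

    def test_matches_from_scratch_recomputation(self, rng):
        for _ in range(25):
            a = random_dna(rng, int(rng.integers(5, 64)))
            b = random_dna(rng, int(rng.integers(5, 64)))
            for c in sliding_overlaps(a, b, 3):
                sub_a = a[c.alpha_start : c.alpha_end]
                sub_b = b[c.beta_start : c.beta_end]
                assert len(sub_a) == len(sub_b) == c.length
                assert c.distance == qgram_distance(
                    profile(sub_a, c.q), profile(sub_b, c.q)
                )

    def test_covers_every_shift_and_admissible_q(self, rng):
        a, b = random_dna(rng, 30), random_dna(rng, 20)
        seen = {(c.shift, c.q) for c in sliding_overlaps(a, b, 5)}
        for shift in range(-19, 30):
            L = min(30, shift + 20) - max(0, shift)
            if L < 5:
                continue
            for q in choose_q(L):
                assert (shift, q) in seen
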