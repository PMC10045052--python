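"""Contig matching: exact enumeration, fast sliding search, scheduling."""

import numpy as np
import pytest

from conftest import brute_match_norm, brute_schedule_weight, random_dna
from pasdist.contigs import (
    MatchPair,
    MatchSet,
    dist_C,
    match_pair_exact,
    match_pair_fast,
    match_sets,
    schedule_matches,
)
from pasdist.samples import ContigSet
from pasdist.simulate import mutate, random_genome


def _pair(iv, weight, alpha_id=0, beta_id=0):
    """MatchPair with a prescribed scheduling weight (= length - edit)."""
    length = iv[1] - iv[0]
    assert 0 <= weight <= length
    return MatchPair(alpha_id, beta_id, iv, (0, length), length - weight)


class TestMatchPairExact:
    def test_identical_contigs_full_match(self, rng):
        s = random_dna(rng, 30)
        mp = match_pair_exact(s, s, 20)
        assert mp.alpha_interval == (0, 30) and mp.beta_interval == (0, 30)
        assert mp.edit == 0 and mp.norm == 0.0

    def test_exact_substring_found(self, rng):
        alpha = random_dna(rng, 60)
        beta = alpha[15:45]
        mp = match_pair_exact(alpha, beta, 20)
        assert mp.edit == 0
        assert mp.alpha_interval == (15, 45) and mp.beta_interval == (0, 30)

    def test_below_threshold_yields_none(self, rng):
        assert match_pair_exact(random_dna(rng, 10), random_dna(rng, 10), 20) is None

    def test_matches_full_enumeration_oracle(self, rng):
        """Minimal normalized distance equals exhaustive search over all
        admissible substring pairs."""
        for trial in range(12):
            la = int(rng.integers(8, 26))
            alpha = random_dna(rng, la)
            if trial % 2:  # related pair: beta extends a mutated piece of alpha
                core = mutate(
                    random_genome(la, rng).__class__("c", alpha[la // 3 :]), 2, rng
                ).seq
                beta = core + random_dna(rng, 5)
            else:
                beta = random_dna(rng, int(rng.integers(8, 26)))
            mp = match_pair_exact(alpha, beta, 5)
            oracle = brute_match_norm(alpha, beta, 5)
            assert mp is not None and oracle is not None
            assert mp.norm == pytest.approx(oracle)


class TestMatchPairFast:
    def test_constructed_suffix_prefix_overlap(self, rng):
        shared = random_dna(rng, 25)
        alpha = random_dna(rng, 30) + shared
        beta = shared + random_dna(rng, 30)
        mp = match_pair_fast(alpha, beta, 20)
        assert mp.edit == 0
        assert mp.alpha_interval == (30, 55) and mp.beta_interval == (0, 25)

    def test_identical_contigs_full_match(self, rng):
        s = random_dna(rng, 50)
        mp = match_pair_fast(s, s, 20)
        assert mp.alpha_interval == (0, 50) and mp.edit == 0

    def test_fast_never_beats_exact(self, rng):
        """Fast mode searches a subset of the exact candidate space."""
        for _ in range(10):
            alpha = random_dna(rng, int(rng.integers(25, 60)))
            beta = random_dna(rng, int(rng.integers(25, 60)))
            f = match_pair_fast(alpha, beta, 20)
            e = match_pair_exact(alpha, beta, 20)
            if f is not None:
                assert e is not None and f.norm >= e.norm - 1e-12


class TestScheduling:
    def test_disjoint_candidates_all_selected(self):
        cands = [_pair((0, 10), 5), _pair((10, 20), 3), _pair((25, 30), 2)]
        assert len(schedule_matches(cands)) == 3

    def test_worked_example(self):
        # intervals [0,30)/w5, [20,50)/w6, [30,70)/w5: optimum picks 1st+3rd
        cands = [_pair((0, 30), 5), _pair((20, 50), 6), _pair((30, 70), 5)]
        chosen = schedule_matches(cands)
        assert sorted(p.alpha_interval for p in chosen) == [(0, 30), (30, 70)]
        assert sum(p.weight for p in chosen) == 10

    def test_empty_input(self):
        assert schedule_matches([]) == []

    def test_matches_subset_enumeration(self, rng):
        """Optimal weight equals brute force over all interval subsets."""
        for _ in range(50):
            n = int(rng.integers(1, 10))
            cands = []
            for _k in range(n):
                s = int(rng.integers(0, 40))
                e = s + int(rng.integers(5, 20))
                w = int(rng.integers(0, e - s + 1))
                cands.append(_pair((s, e), w))
            got = sum(p.weight for p in schedule_matches(cands))
            want = brute_schedule_weight(
                [(p.alpha_interval, p.weight) for p in cands]
            )
            assert got == want


class TestMatchSets:
    def test_identical_sets_fully_matched(self, rng):
        CA = ContigSet([random_dna(rng, 40), random_dna(rng, 55)])
        ms = match_sets(CA, CA)
        assert {p.alpha_interval for p in ms} == {(0, 40), (0, 55)}
        assert all(p.edit == 0 for p in ms)

    def test_empty_target_set(self, rng):
        CA = ContigSet([random_dna(rng, 40)])
        assert len(match_sets(CA, ContigSet())) == 0

    def test_alpha_disjointness_enforced(self):
        with pytest.raises(ValueError):
            MatchSet((_pair((0, 30), 5), _pair((20, 50), 5)))

    def test_small_instance_matches_brute_force_assignment(self, rng):
        """Scheduled weight per contig equals the best disjoint subset of
        the per-target candidates (exact mode, no norm cutoff)."""
        from pasdist.contigs import match_pair_exact

        for _ in range(6):
            CA = ContigSet([random_dna(rng, int(rng.integers(15, 30))) for _ in range(2)])
            CB = ContigSet([random_dna(rng, int(rng.integers(15, 30))) for _ in range(3)])
            ms = match_sets(CA, CB, mode="exact", min_overlap=5, max_norm=None)
            for i, alpha in enumerate(CA):
                cands = []
                for beta in CB:
                    mp = match_pair_exact(alpha, beta, 5)
                    if mp is not None:
                        cands.append((mp.alpha_interval, mp.weight))
                got = sum(p.weight for p in ms if p.alpha_id == i)
                assert got == brute_schedule_weight(cands)


class TestDistC:
    def test_identical_sets_are_zero(self, rng):
        CA = ContigSet([random_dna(rng, 50), random_dna(rng, 60)])
        assert dist_C(CA, CA) == 0.0

    def test_unrelated_sets_hit_empty_match_convention(self, rng):
        CA = ContigSet([random_dna(rng, 120)])
        CB = ContigSet([random_dna(rng, 120)])
        assert dist_C(CA, CB) == 1.0

    def test_single_pair_arithmetic(self, rng):
        base = random_dna(rng, 25)
        mutated = list(base)
        mutated[5] = {"a": "c"}.get(mutated[5], "a")
        mutated[15] = {"g": "t"}.get(mutated[15], "g")
        CA, CB = ContigSet([base]), ContigSet(["".join(mutated)])
        assert dist_C(CA, CB) == pytest.approx(2 / 25)

    def test_decreases_as_mutations_are_reverted(self, rng):
        g = random_genome(200, rng)
        CA = ContigSet([g.seq])
        vals = []
        for m in (40, 20, 0):
            CB = ContigSet([mutate(g, m, np.random.default_rng(99)).seq])
            vals.append(dist_C(CA, CB))
        assert vals[0] >= vals[1] >= vals[2] == 0.0
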