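"""Neighbor joining, Newick round trips, and tree/matrix comparison metrics."""

import numpy as np
import pytest

from pasdist.phylo import (
    Clustering,
    PhyloTree,
    cut_tree,
    fowlkes_mallows,
    neighbor_joining,
    pearson,
    read_newick,
    triplets_distance,
    write_newick,
)
from pasdist.samples import DistanceMatrix


def _matrix(labels, rows):
    return DistanceMatrix(labels, np.array(rows, dtype=float))


def _patristic(tree: PhyloTree):
    rooted = tree.root
    tips = {t.name: t for t in rooted.tips()}
    out = {}
    names = sorted(tips)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out[(a, b)] = tips[a].distance(tips[b])
    return out


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_tree(self):
        # generating tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        m = _matrix(
            list("ABCD"),
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
        )
        tree = neighbor_joining(m)
        pat = _patristic(tree)
        for (a, b), d in pat.items():
            assert d == pytest.approx(m[(a, b)])
        truth = PhyloTree.from_newick("((A:1,B:2):1,(C:3,D:4):0);")
        assert triplets_distance(tree, truth) == 0

    def test_two_taxa_single_split_edge(self):
        tree = neighbor_joining(_matrix(["A", "B"], [[0, 5], [5, 0]]))
        pat = _patristic(tree)
        assert pat[("A", "B")] == pytest.approx(5.0)

    def test_three_taxa_closed_form(self):
        # d(AB)=4, d(AC)=6, d(BC)=8 -> a=1, b=3, c=5 by the half-sum formulas
        tree = neighbor_joining(_matrix(list("ABC"), [[0, 4, 6], [4, 0, 8], [6, 8, 0]]))
        pat = _patristic(tree)
        assert pat[("A", "B")] == pytest.approx(4.0)
        assert pat[("A", "C")] == pytest.approx(6.0)
        assert pat[("B", "C")] == pytest.approx(8.0)

    def test_non_symmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(
                DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
            )


class TestNewick:
    def test_round_trip_preserves_patristic_distances(self, tmp_path, rng):
        from pasdist.simulate import make_dataset

        ds = make_dataset(n_samples=10, genome_len=60, mutations=(1, 5),
                          l=10, c=1.0, contig_fraction=0, seed=3)
        truth = PhyloTree.from_newick(ds.true_tree_newick)
        p = tmp_path / "t.nwk"
        write_newick(truth, p)
        back = read_newick(p)
        assert triplets_distance(truth, back) == 0
        pa, pb = _patristic(truth), _patristic(back)
        for k in pa:
            assert pa[k] == pytest.approx(pb[k])

    def test_labels_with_spaces_survive_round_trip(self):
        m = _matrix(["tax one", "tax two", "tax three"],
                    [[0, 4, 6], [4, 0, 8], [6, 8, 0]])
        t = neighbor_joining(m)
        back = PhyloTree.from_newick(t.newick())
        assert sorted(back.leaf_labels) == sorted(m.labels)

    def test_negative_lengths_clamped_on_output(self):
        t = PhyloTree.from_newick("((A:1,B:-0.5):1,(C:1,D:1):1);")
        assert "-0.5" not in t.newick()


class TestPearson:
    def test_identity_and_affine_invariance(self):
        m = _matrix(list("ABC"), [[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        assert pearson(m, m) == pytest.approx(1.0)
        v = m.values * 2.5 + 7
        np.fill_diagonal(v, 0)
        assert pearson(m, DistanceMatrix(m.labels, v)) == pytest.approx(1.0)

    def test_constant_matrix_undefined(self):
        m = _matrix(list("ABC"), [[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        c = _matrix(list("ABC"), [[0, 5, 5], [5, 0, 5], [5, 5, 0]])
        assert np.isnan(pearson(m, c))

    def test_label_mismatch_rejected(self):
        m1 = _matrix(list("ABC"), [[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        m2 = _matrix(list("ABD"), [[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        with pytest.raises(ValueError):
            pearson(m1, m2)


class TestCutTree:
    def test_extreme_cuts(self):
        t = PhyloTree.from_newick("((A:1,B:1):2,(C:1,D:1):2);")
        one = cut_tree(t, 1)
        assert one.blocks == (frozenset("ABCD"),)
        singles = cut_tree(t, 4)
        assert sorted(map(len, singles.blocks)) == [1, 1, 1, 1]

    def test_long_internal_edge_splits_first(self):
        t = PhyloTree.from_newick("((A:1,B:1):5,(C:1,D:1):5);")
        two = cut_tree(t, 2)
        assert set(two.blocks) == {frozenset("AB"), frozenset("CD")}


class TestFowlkesMallows:
    def _c(self, *blocks):
        return Clustering(tuple(frozenset(b) for b in blocks))

    def test_identical_clusterings(self):
        c = self._c("AB", "CD")
        assert fowlkes_mallows(c, c) == 1.0

    def test_disjoint_pairings(self):
        assert fowlkes_mallows(self._c("AB", "CD"), self._c("AC", "BD")) == 0.0

    def test_worked_example(self):
        # TP = 1 (AB); co-pairs: 2 in the first clustering, 3 in the second
        got = fowlkes_mallows(self._c("AB", "CD"), self._c("ABC", "D"))
        assert got == pytest.approx(1 / np.sqrt(6))

    def test_singletons_agree_trivially(self):
        s = self._c("A", "B", "C")
        assert fowlkes_mallows(s, s) == 1.0

    def test_cross_check_against_sklearn(self, rng):
        from sklearn.metrics import fowlkes_mallows_score

        labels = [f"x{i}" for i in range(12)]
        for _ in range(20):
            a1 = rng.integers(0, 3, size=12)
            a2 = rng.integers(0, 4, size=12)
            c1 = self._c(*[
                {l for l, g in zip(labels, a1) if g == k} for k in set(a1)
            ])
            c2 = self._c(*[
                {l for l, g in zip(labels, a2) if g == k} for k in set(a2)
            ])
            assert fowlkes_mallows(c1, c2) == pytest.approx(
                fowlkes_mallows_score(a1, a2)
            )


class TestTripletsDistance:
    def test_identical_trees(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert triplets_distance(t, t) == 0

    def test_conflicting_quartets_disagree_everywhere(self):
        t1 = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert triplets_distance(t1, t2) == 4

    def test_star_against_itself(self):
        s1 = PhyloTree.from_newick("(A:1,B:1,C:1,D:1);")
        s2 = PhyloTree.from_newick("(A:1,B:1,C:1,D:1);")
        assert triplets_distance(s1, s2) == 0

    def test_leaf_set_mismatch_rejected(self):
        t1 = PhyloTree.from_newick("((A:1,B:1):1,C:1);")
        t2 = PhyloTree.from_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(ValueError):
            triplets_distance(t1, t2)

    def test_bounded_by_triple_count(self, rng):
        from pasdist.simulate import make_dataset
        import math

        ds1 = make_dataset(n_samples=8, genome_len=60, mutations=(1, 4),
                           l=10, c=1.0, contig_fraction=0, seed=5)
        ds2 = make_dataset(n_samples=8, genome_len=60, mutations=(1, 4),
                           l=10, c=1.0, contig_fraction=0, seed=6)
        t1 = PhyloTree.from_newick(ds1.true_tree_newick)
        t2 = PhyloTree.from_newick(ds2.true_tree_newick)
        assert 0 <= triplets_distance(t1, t2) <= math.comb(8, 3)
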