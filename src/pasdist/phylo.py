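"""Tree building and tree/matrix comparison.

Neighbor joining (Saitou-Nei, exact on additive matrices) turns a
distance matrix into an unrooted tree.  Estimated and reference results
are compared three ways: Pearson correlation of the pairwise distances,
the Fowlkes-Mallows index of the clusterings obtained by cutting both
trees into k clusters, and the triplet distance (number of 3-leaf
subsets with differing induced topologies).

Trees are unrooted; where a rooted view is needed (cutting, triplets)
they are midpoint-rooted, with negative NJ branch lengths clamped to 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import skbio
from scipy import stats

from .samples import DistanceMatrix


class PhyloTree:
    """A leaf-labelled tree with branch lengths (thin scikit-bio wrapper)."""

    def __init__(self, root: skbio.TreeNode) -> None:
        self.root = root
        tips = [t.name for t in root.tips()]
        if len(set(tips)) != len(tips):
            raise ValueError("duplicate leaf labels")
        self.leaf_labels = sorted(tips)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        return cls(skbio.TreeNode.read([newick]))

    def newick(self, clamp_negative: bool = True) -> str:
        tree = self.root.copy()
        if clamp_negative:
            for node in tree.traverse():
                if node.length is not None and node.length < 0:
                    node.length = 0.0
        return str(tree).strip()

    def midpoint_rooted(self) -> skbio.TreeNode:
        tree = self.root.copy()
        for node in tree.traverse():
            if node.length is not None and node.length < 0:
                node.length = 0.0
        if len(self.leaf_labels) <= 2:
            return tree
        return tree.root_at_midpoint()


def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree of a distance matrix.

    On an additive matrix this recovers the generating topology and
    branch lengths exactly.  For two taxa the tree is a single edge
    split evenly.
    """
    n = len(matrix.labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    if n == 2:
        d = matrix.values[0, 1]
        a, b = matrix.labels
        return PhyloTree.from_newick(f"({a}:{d / 2},{b}:{d / 2});")
    dm = skbio.DistanceMatrix(matrix.values, ids=matrix.labels)
    return PhyloTree(skbio.tree.nj(dm))


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(tree.newick() + "\n")


def read_newick(path: str | Path) -> PhyloTree:
    return PhyloTree(skbio.TreeNode.read(str(path)))


def pearson(m1: DistanceMatrix, m2: DistanceMatrix) -> float:
    """Pearson correlation over the strictly-upper-triangle distances.

    Returns ``nan`` when either vector has zero variance (all sequences
    equidistant — the correlation is undefined).
    """
    if m1.labels != m2.labels:
        raise ValueError("matrices have different labels")
    if len(m1.labels) < 3:
        raise ValueError("need at least three taxa")
    v1, v2 = m1.condensed(), m2.condensed()
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        return float("nan")
    return float(stats.pearsonr(v1, v2).statistic)


@dataclass(frozen=True)
class Clustering:
    """A partition of leaf labels into non-empty blocks."""

    blocks: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for b in self.blocks:
            if not b:
                raise ValueError("empty block")
            if b & seen:
                raise ValueError("blocks are not disjoint")
            seen |= b

    @property
    def labels(self) -> frozenset[str]:
        return frozenset().union(*self.blocks)

    def assignment(self) -> dict[str, int]:
        return {x: i for i, b in enumerate(self.blocks) for x in b}


def _node_heights(tree: skbio.TreeNode) -> dict[int, float]:
    heights: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_tip():
            heights[id(node)] = 0.0
        else:
            heights[id(node)] = max(
                heights[id(ch)] + max(ch.length or 0.0, 0.0) for ch in node.children
            )
    return heights


def cut_tree(tree: PhyloTree, k: int) -> Clustering:
    """Cut a tree into exactly ``k`` clusters of leaves.

    The tree is midpoint-rooted and treated as a dendrogram by node
    height (greatest leaf-to-node path length); the k-1 highest internal
    nodes are dissolved, equivalently the current highest cluster is
    split repeatedly until k clusters remain.
    """
    n = len(tree.leaf_labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    rooted = tree.midpoint_rooted()
    heights = _node_heights(rooted)
    order = {id(node): i for i, node in enumerate(rooted.preorder())}
    roots = [rooted]
    while len(roots) < k:
        splittable = [r for r in roots if not r.is_tip()]
        target = max(splittable, key=lambda r: (heights[id(r)], -order[id(r)]))
        roots.remove(target)
        roots.extend(target.children)
    blocks = tuple(frozenset(t.name for t in r.tips()) or frozenset([r.name]) for r in roots)
    return Clustering(blocks)


def fowlkes_mallows(c1: Clustering, c2: Clustering) -> float:
    """Fowlkes-Mallows index ``B = TP / sqrt((TP+FP)(TP+FN))`` over
    co-clustered pairs.

    Degenerate cases: if neither clustering co-clusters any pair (e.g.
    all-singleton vs all-singleton) they agree trivially and B = 1; if
    exactly one does, B = 0.
    """
    if c1.labels != c2.labels:
        raise ValueError("clusterings cover different label sets")
    a1, a2 = c1.assignment(), c2.assignment()
    from collections import Counter

    joint = Counter((a1[x], a2[x]) for x in a1)
    n1 = Counter(a1.values())
    n2 = Counter(a2.values())
    tp = sum(v * (v - 1) // 2 for v in joint.values())
    p1 = sum(v * (v - 1) // 2 for v in n1.values())  # TP + FP
    p2 = sum(v * (v - 1) // 2 for v in n2.values())  # TP + FN
    if p1 == 0 and p2 == 0:
        return 1.0
    if p1 == 0 or p2 == 0:
        return 0.0
    return tp / math.sqrt(p1 * p2)


def _cherries(tree: PhyloTree) -> dict[frozenset[str], frozenset[str] | None]:
    """For every 3-leaf subset, the pair grouped away from the third leaf
    (``None`` for an unresolved star); from the midpoint-rooted tree."""
    rooted = tree.midpoint_rooted()
    tips = {t.name: t for t in rooted.tips()}
    # ancestor chains as id-sets for O(1) LCA-node lookup
    chains: dict[str, list] = {}
    for name, tip in tips.items():
        chain = [tip]
        node = tip
        while node.parent is not None:
            node = node.parent
            chain.append(node)
        chains[name] = chain

    depth = {id(node): i for i, node in enumerate(rooted.preorder())}

    def lca(x: str, y: str):
        ids_y = {id(n) for n in chains[y]}
        for node in chains[x]:
            if id(node) in ids_y:
                return node
        raise RuntimeError("disconnected tree")

    out: dict[frozenset[str], frozenset[str] | None] = {}
    names = sorted(tips)
    lca_cache = {
        frozenset((x, y)): lca(x, y) for x, y in itertools.combinations(names, 2)
    }
    for trio in itertools.combinations(names, 3):
        x, y, z = trio
        pairs = [frozenset((x, y)), frozenset((x, z)), frozenset((y, z))]
        nodes = [lca_cache[p] for p in pairs]
        deepest = max(range(3), key=lambda i: depth[id(nodes[i])])
        others = [i for i in range(3) if i != deepest]
        if all(nodes[deepest] is nodes[i] for i in others):
            out[frozenset(trio)] = None  # unresolved
        else:
            out[frozenset(trio)] = pairs[deepest]
    return out


def triplets_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Number of 3-leaf subsets whose induced (midpoint-rooted) topologies
    differ between the two trees; unresolved agrees only with unresolved."""
    if set(t1.leaf_labels) != set(t2.leaf_labels):
        raise ValueError("trees have different leaf sets")
    if len(t1.leaf_labels) < 3:
        raise ValueError("need at least three leaves")
    ch1, ch2 = _cherries(t1), _cherries(t2)
    return sum(1 for trio in ch1 if ch1[trio] != ch2[trio])
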