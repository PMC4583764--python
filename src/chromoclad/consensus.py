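"""Bipartitions, consensus trees and topological distance.

Removing an internal edge of an unrooted tree splits the leaves into two
sets — a bipartition.  A set of equally parsimonious trees is summarized
by the bipartitions they share: the *strict* consensus keeps the splits
present in every tree, the *majority-rule* consensus keeps the splits
present in more than a threshold fraction (strictly greater, so at the
usual 0.5 threshold a split occurring in exactly half the trees is
excluded — the convention of classic parsimony software).  Splits that
pass a strict majority threshold are pairwise compatible, so the consensus
tree always exists; it is generally multifurcating.

Bipartitions are canonicalized to the side not containing a fixed
reference leaf (the lexicographically smallest label), which makes split
equality orientation-independent.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

from .trees import Node, Tree, TreeError


def bipartitions(tree: Tree) -> frozenset[frozenset[str]]:
    """The non-trivial splits of a tree, canonicalized.

    For an unrooted binary tree over n leaves this has exactly n-3
    elements (one per internal edge).
    """

    return tree.splits()


def _check_same_leaves(trees: Sequence[Tree]) -> frozenset[str]:
    if not trees:
        raise ValueError("need at least one tree")
    leaves = trees[0].leaf_labels
    for i, t in enumerate(trees[1:], start=2):
        if t.leaf_labels != leaves:
            raise ValueError(
                f"tree {i} has a different leaf set: "
                f"{sorted(t.leaf_labels ^ leaves)} not shared")
    return leaves


def tree_from_splits(splits: frozenset[frozenset[str]],
                     leaves: frozenset[str]) -> Tree:
    """Build the (possibly multifurcating) unrooted tree containing exactly
    the given pairwise compatible splits."""

    ref = min(leaves)
    clades = []
    for s in splits:
        clade = s if ref not in s else leaves - s
        clades.append(set(clade))
    for a in clades:
        for b in clades:
            if a & b and not (a <= b or b <= a):
                raise ValueError(f"incompatible splits: {sorted(a)} vs {sorted(b)}")

    ingroup = set(leaves) - {ref}

    def build(members: set, pool: list[set]) -> list[Node]:
        """Children nodes spanning ``members``, nesting the clades in ``pool``."""
        maximal: list[set] = []
        for c in sorted(pool, key=len, reverse=True):
            if c < members and not any(c <= m for m in maximal):
                maximal.append(c)
        covered = set().union(*maximal) if maximal else set()
        children = []
        for m in sorted(maximal, key=lambda s: sorted(s)):
            sub = build(m, [c for c in pool if c < m])
            children.append(Node(children=sub))
        for lab in sorted(members - covered):
            children.append(Node(label=lab))
        return children

    root = Node(children=[Node(label=ref)] + build(ingroup, clades))
    return Tree(root, rooted=False)


def split_frequencies(trees: Sequence[Tree]) -> dict[frozenset[str], float]:
    """Fraction of input trees containing each split."""
    _check_same_leaves(trees)
    counts: Counter = Counter()
    for t in trees:
        for s in t.splits():
            counts[s] += 1
    return {s: c / len(trees) for s, c in counts.items()}


def majority_rule_consensus(trees: Sequence[Tree], threshold: float = 0.5) -> Tree:
    """Splits occurring in strictly more than ``threshold`` of the trees.

    ``threshold`` must lie in [0.5, 1); below a strict majority the
    retained splits need not be compatible.
    """

    if not 0.5 <= threshold < 1:
        raise ValueError(f"threshold must be in [0.5, 1), got {threshold}")
    leaves = _check_same_leaves(trees)
    freqs = split_frequencies(trees)
    keep = frozenset(s for s, f in freqs.items() if f > threshold)
    return tree_from_splits(keep, leaves)


def strict_consensus(trees: Sequence[Tree]) -> Tree:
    """Splits present in every input tree."""
    leaves = _check_same_leaves(trees)
    freqs = split_frequencies(trees)
    keep = frozenset(s for s, f in freqs.items() if f == 1.0)
    return tree_from_splits(keep, leaves)


def robinson_foulds(tree_a: Tree, tree_b: Tree) -> int:
    """Size of the symmetric difference of the two split sets.

    Zero iff the unrooted topologies are identical; at most 2(n-3) for
    binary trees.
    """

    if tree_a.leaf_labels != tree_b.leaf_labels:
        raise ValueError(
            "trees have different leaf sets: "
            f"{sorted(tree_a.leaf_labels ^ tree_b.leaf_labels)} not shared")
    return len(tree_a.splits() ^ tree_b.splits())


def polytomy_taxa(tree: Tree) -> frozenset[str]:
    """Leaves attached directly to a multifurcating node.

    Used to ask *where* a consensus is unresolved: a leaf returned here
    has an uncertain attachment among the subtrees meeting at that
    polytomy.
    """

    out = set()
    for node in tree.root.postorder():
        if node.is_leaf:
            continue
        max_children = (2 if tree.rooted else 3) if node is tree.root else 2
        if len(node.children) > max_children:
            for c in node.children:
                if c.is_leaf:
                    out.add(c.label)
    return frozenset(out)
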