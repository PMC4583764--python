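"""Phylogenetic tree container used throughout the package.

Trees here are purely topological: the characters are discrete
rearrangement events, so no branch lengths are estimated anywhere in the
analysis pipeline.  Branch lengths are carried only when a tree comes from
the synthetic-data generator, where they parameterize the gain/loss
process.

A :class:`Tree` wraps a simple node structure.  A *rooted* tree has a root
of out-degree >= 2; an *unrooted* tree is stored with a basal node of
degree >= 3 (the conventional trifurcation for binary unrooted trees).
Polytomies are allowed everywhere — consensus trees are typically
multifurcating.

Topological identity is defined the way tree-comparison methods define it:
two unrooted trees are equal iff they induce the same set of bipartitions
of the same leaf set; two rooted trees are equal iff they have the same
clade sets.  Newick parsing is delegated to dendropy.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import dendropy


class TreeError(ValueError):
    """Raised for structurally invalid trees or invalid tree operations."""


class Node:
    """A tree node: a leaf (with a label) or an internal node (with children)."""

    __slots__ = ("label", "children", "length")

    def __init__(self, label: Optional[str] = None,
                 children: Optional[Iterable["Node"]] = None,
                 length: Optional[float] = None):
        self.label = label
        self.children: list[Node] = list(children) if children else []
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def clone(self) -> "Node":
        return Node(self.label, [c.clone() for c in self.children], self.length)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r})" if self.is_leaf else f"Node(<{len(self.children)} children>)"


def leaf(label: str, length: Optional[float] = None) -> Node:
    return Node(label=label, length=length)


def internal(children: Iterable[Node], length: Optional[float] = None) -> Node:
    return Node(children=children, length=length)


class Tree:
    """A rooted or unrooted topological tree over uniquely labelled leaves."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        labels = [n.label for n in root.postorder() if n.is_leaf]
        if any(lab is None or lab == "" for lab in labels):
            raise TreeError("every leaf must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")
        if not rooted and len(labels) >= 3 and len(self.root.children) == 2:
            raise TreeError("unrooted tree must have a basal node of degree >= 3")
        self._labels = frozenset(labels)

    # ------------------------------------------------------------------
    # basic structure
    # ------------------------------------------------------------------

    @property
    def leaf_labels(self) -> frozenset[str]:
        return self._labels

    @property
    def n_leaves(self) -> int:
        return len(self._labels)

    def is_binary(self) -> bool:
        """True if fully resolved (rooted: all out-degrees 2; unrooted: basal 3)."""
        for i, node in enumerate(self.root.postorder()):
            if node.is_leaf:
                continue
            if node is self.root:
                continue
            if len(node.children) != 2:
                return False
        k = len(self.root.children)
        if self.rooted:
            return k == 2 or self.n_leaves == 1
        return k == 3 or self.n_leaves <= 3

    def copy(self) -> "Tree":
        return Tree(self.root.clone(), self.rooted)

    # ------------------------------------------------------------------
    # splits and clades
    # ------------------------------------------------------------------

    def clades(self, trivial: bool = False) -> frozenset[frozenset[str]]:
        """Leaf sets below each node (rooted perspective).

        Excludes the root's full set; excludes single leaves unless
        ``trivial`` is set.
        """
        out = set()

        def rec(node: Node) -> frozenset:
            if node.is_leaf:
                s = frozenset([node.label])
            else:
                s = frozenset().union(*(rec(c) for c in node.children))
            if node is not self.root and (trivial or len(s) > 1):
                out.add(s)
            return s

        rec(self.root)
        return frozenset(out)

    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized to the side that does
        not contain the lexicographically smallest leaf label."""
        ref = min(self._labels)
        full = self._labels
        out = set()
        for clade in self.clades():
            if len(clade) >= len(full) - 1:
                continue
            out.add(clade if ref not in clade else full - clade)
        return frozenset(out)

    # ------------------------------------------------------------------
    # equality / hashing: purely topological
    # ------------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Tree):
            return NotImplemented
        if self.rooted != other.rooted or self._labels != other._labels:
            return False
        if self.rooted:
            return self.clades() == other.clades()
        return self.splits() == other.splits()

    def __hash__(self) -> int:
        key = self.clades() if self.rooted else self.splits()
        return hash((self.rooted, self._labels, key))

    # ------------------------------------------------------------------
    # rooting
    # ------------------------------------------------------------------

    def unrooted(self) -> "Tree":
        """Suppress a bifurcating root, yielding the unrooted topology."""
        if not self.rooted:
            return self.copy()
        root = self.root.clone()
        while len(root.children) == 2 and not all(c.is_leaf for c in root.children):
            a, b = root.children
            if a.is_leaf:
                a, b = b, a
            # fuse: b (and the root edge) hangs off a's node
            a.children.append(b)
            root = a
        return Tree(root, rooted=False)

    # ------------------------------------------------------------------
    # Newick
    # ------------------------------------------------------------------

    def to_newick(self, lengths: bool = False) -> str:
        def rec(node: Node) -> str:
            if node.is_leaf:
                s = node.label
            else:
                s = "(" + ",".join(rec(c) for c in node.children) + ")"
            if lengths and node.length is not None:
                s += f":{node.length:.10g}"
            return s

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str, rooted: Optional[bool] = None) -> "Tree":
        """Parse one Newick tree (via dendropy).

        If ``rooted`` is not given, a basal bifurcation is read as a rooted
        tree and a basal multifurcation as unrooted — the usual convention.
        """
        try:
            dtree = dendropy.Tree.get(data=text, schema="newick",
                                      suppress_internal_node_taxa=True)
        except Exception as exc:
            raise TreeError(f"could not parse Newick: {exc}") from exc

        def convert(dnode) -> Node:
            if dnode.is_leaf():
                lab = dnode.taxon.label if dnode.taxon else dnode.label
                return Node(label=lab, length=dnode.edge.length)
            return Node(children=[convert(c) for c in dnode.child_nodes()],
                        length=dnode.edge.length)

        root = convert(dtree.seed_node)
        if rooted is None:
            rooted = len(root.children) == 2
        return cls(root, rooted=rooted)


def read_newick_trees(text: str, rooted: Optional[bool] = None) -> list[Tree]:
    """Parse a multi-tree Newick string/file content, one tree per statement."""
    trees = []
    for chunk in text.split(";"):
        if chunk.strip():
            trees.append(Tree.from_newick(chunk + ";", rooted=rooted))
    return trees
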