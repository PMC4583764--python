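"""Small parsimony and exact search for most-parsimonious trees.

Characters are unordered, equally weighted and binary, so the length of a
tree is the Fitch length: the sum over characters of the minimum number of
state changes required on that topology.  For fully resolved trees this is
computed with the classic Fitch set pass; all 0/1 state sets for all
characters are packed two bits per character into one Python integer per
node, so one post-order pass costs one bitwise merge per internal node
regardless of the number of characters.  Trees with polytomies are scored
exactly with the unit-cost Sankoff dynamic program (minimization over
ancestral states at every node, whatever its degree).

The search for *all* most-parsimonious topologies is exact.  Naive
exhaustive enumeration is provided as an oracle for small problems (the
number of unrooted binary topologies is the double factorial (2n-5)!!);
the production search is depth-first branch-and-bound over stepwise leaf
insertion, which visits every topology implicitly and is therefore
equivalent to exhaustive search while pruning provably suboptimal
subtrees.  The lower bound used is the partial-tree Fitch length (adding
leaves never decreases parsimony length) plus one step for every character
that is still constant on the partial taxon set but variable on the full
set.  Ties are never discarded: a branch is pruned only when its bound
strictly exceeds the best length found so far, so the returned tree set is
provably complete.

Equally parsimonious binary trees often differ only in branches that no
minimal reconstruction ever places a change on.  :func:`condense_trees`
collapses such zero-maximum-length branches and deduplicates, which is how
classic parsimony software counts "distinct" MP trees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .characters import CharacterMatrix
from .trees import Node, Tree, TreeError

ENUMERATION_CAP = 10  # (2*10-5)!! = 2,027,025 topologies: the streaming limit
SEARCH_CAP = 16


# ---------------------------------------------------------------------------
# packed Fitch scoring
# ---------------------------------------------------------------------------

def _pack_states(matrix: CharacterMatrix) -> tuple[dict[str, int], int, int]:
    """Per-taxon packed state sets.

    Character ``c`` occupies bit pair ``2c``: bit 0 set means "state 0 is in
    the Fitch set", bit 1 means "state 1 is".  Returns (packed-per-taxon,
    low-bit mask, n_characters).
    """

    n_char = matrix.n_characters
    lo_mask = int("01" * n_char, 2) if n_char else 0
    packed = {}
    for i, taxon in enumerate(matrix.taxa):
        value = 0
        for state in matrix.states[i]:
            value = (value << 2) | (2 if state else 1)
        packed[taxon] = value
    return packed, lo_mask, n_char


def _fitch_merge(a: int, b: int, lo_mask: int) -> tuple[int, int]:
    """One Fitch combine: intersection where non-empty, else union (+1 step)."""
    inter = a & b
    nonempty = (inter | (inter >> 1)) & lo_mask
    empty = lo_mask & ~nonempty
    fill = empty | (empty << 1)
    return inter | ((a | b) & fill), empty.bit_count()


def _require_same_leaves(tree: Tree, matrix: CharacterMatrix) -> None:
    leaves = tree.leaf_labels
    taxa = frozenset(matrix.taxa)
    if leaves != taxa:
        missing = sorted(taxa - leaves)
        extra = sorted(leaves - taxa)
        raise ValueError(
            "tree leaves and matrix taxa differ: "
            f"missing from tree {missing}, not in matrix {extra}")


def fitch_length(tree: Tree, matrix: CharacterMatrix) -> int:
    """Minimum total number of state changes of ``matrix`` on ``tree``.

    Independent of rooting.  Fully resolved trees take the packed Fitch
    pass; multifurcating trees fall back to the exact Sankoff program.
    """

    _require_same_leaves(tree, matrix)
    if not tree.is_binary():
        costs = sankoff_costs(tree, matrix)
        return int(costs.min(axis=1).sum())
    packed, lo_mask, _ = _pack_states(matrix)
    total = 0

    def rec(node: Node) -> int:
        nonlocal total
        if node.is_leaf:
            return packed[node.label]
        it = iter(node.children)
        value = rec(next(it))
        for child in it:
            value, steps = _fitch_merge(value, rec(child), lo_mask)
            total += steps
        return value

    rec(tree.root)
    return total


def sankoff_costs(tree: Tree, matrix: CharacterMatrix) -> np.ndarray:
    """Root-conditional minimal change counts, shape (n_characters, 2).

    Entry ``[c, s]`` is the minimum number of changes of character ``c``
    given the node at the tree's root position is in state ``s``.  Exact on
    polytomies.
    """

    _require_same_leaves(tree, matrix)
    n_char = matrix.n_characters
    big = np.iinfo(np.int64).max // 4
    taxon_row = {t: i for i, t in enumerate(matrix.taxa)}

    def rec(node: Node) -> np.ndarray:
        if node.is_leaf:
            states = matrix.states[taxon_row[node.label]].astype(np.int64)
            cost = np.full((n_char, 2), big, dtype=np.int64)
            cost[np.arange(n_char), states] = 0
            return cost
        total = np.zeros((n_char, 2), dtype=np.int64)
        for child in node.children:
            c = rec(child)
            total[:, 0] += np.minimum(c[:, 0], c[:, 1] + 1)
            total[:, 1] += np.minimum(c[:, 1], c[:, 0] + 1)
        return total

    return rec(tree.root)


# ---------------------------------------------------------------------------
# internal integer-tuple representation for the search
# ---------------------------------------------------------------------------
# A partial/complete unrooted tree over taxa 0..k-1 is a nested tuple whose
# base node is a trifurcation; leaves are taxon indices.  Inserting taxon k
# on every edge of every tree over k leaves generates every topology over
# k+1 leaves exactly once, which is what makes both the enumerator and the
# branch-and-bound search complete and duplicate-free.

_TupleTree = tuple


def _insertions(tree: _TupleTree, new_leaf: int) -> list[_TupleTree]:
    def inside(node):
        alts = [(node, new_leaf)]
        if not isinstance(node, int):
            for i, child in enumerate(node):
                for alt in inside(child):
                    alts.append(tuple(alt if j == i else c for j, c in enumerate(node)))
        return alts

    out = []
    for i, child in enumerate(tree):
        for alt in inside(child):
            out.append(tuple(alt if j == i else c for j, c in enumerate(tree)))
    return out


def _tuple_to_tree(tree: _TupleTree, taxa: Sequence[str]) -> Tree:
    def build(node) -> Node:
        if isinstance(node, int):
            return Node(label=taxa[node])
        return Node(children=[build(c) for c in node])

    return Tree(build(tree), rooted=False)


class _PackedScorer:
    """Fitch length of integer-tuple trees against packed leaf states."""

    def __init__(self, matrix: CharacterMatrix):
        packed, self.lo_mask, _ = _pack_states(matrix)
        self.leaf_bits = [packed[t] for t in matrix.taxa]

    def length(self, tree: _TupleTree) -> int:
        total = 0
        lo = self.lo_mask

        def rec(node):
            nonlocal total
            if isinstance(node, int):
                return self.leaf_bits[node]
            it = iter(node)
            value = rec(next(it))
            for child in it:
                value, steps = _fitch_merge(value, rec(child), lo)
                total += steps
            return value

        rec(tree)
        return total


# ---------------------------------------------------------------------------
# enumeration oracle
# ---------------------------------------------------------------------------

def n_unrooted_topologies(n_taxa: int) -> int:
    """(2n-5)!! — the count of distinct unrooted binary topologies."""
    out = 1
    for k in range(3, 2 * n_taxa - 4, 2):
        out *= k
    return out


def enumerate_unrooted_trees(taxa: Sequence[str],
                             cap: int = ENUMERATION_CAP) -> Iterator[Tree]:
    """Yield every unrooted binary topology over ``taxa`` exactly once.

    Intended as a ground-truth oracle for small problems; refuses more than
    ``cap`` taxa (the count grows as (2n-5)!!), pointing at
    :func:`branch_and_bound_search` instead.
    """

    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa for an unrooted topology")
    if len(taxa) > cap:
        raise ValueError(
            f"{len(taxa)} taxa would enumerate {n_unrooted_topologies(len(taxa)):,} "
            f"topologies (cap {cap}); use branch_and_bound_search for an exact "
            "search at this size")

    def grow(tree: _TupleTree, k: int) -> Iterator[_TupleTree]:
        if k == len(taxa):
            yield tree
            return
        for bigger in _insertions(tree, k):
            yield from grow(bigger, k + 1)

    for tup in grow((0, 1, 2), 3):
        yield _tuple_to_tree(tup, taxa)


# ---------------------------------------------------------------------------
# stepwise addition (greedy upper bound)
# ---------------------------------------------------------------------------

def stepwise_addition_bound(matrix: CharacterMatrix,
                            seed_order: Optional[Sequence[str]] = None
                            ) -> tuple[Tree, int]:
    """Greedy stepwise-addition tree and its length (an upper bound).

    Taxa are inserted in ``seed_order`` (default: matrix order), each on the
    edge minimizing the Fitch length of the grown tree; ties break to the
    first minimal insertion point, so the result is deterministic.
    """

    order = list(seed_order) if seed_order is not None else list(matrix.taxa)
    if sorted(order) != sorted(matrix.taxa):
        raise ValueError("seed_order must be a permutation of the matrix taxa")
    if len(order) < 3:
        raise ValueError("need at least 3 taxa")
    index = {t: i for i, t in enumerate(matrix.taxa)}
    scorer = _PackedScorer(matrix)
    current: _TupleTree = tuple(index[t] for t in order[:3])
    for taxon in order[3:]:
        candidates = _insertions(current, index[taxon])
        current = min(candidates, key=scorer.length)
    length = scorer.length(current)
    return _tuple_to_tree(current, matrix.taxa), length


# ---------------------------------------------------------------------------
# branch and bound
# ---------------------------------------------------------------------------

@dataclass
class MPSearchResult:
    """Outcome of an exact most-parsimonious tree search.

    ``trees`` is the complete set of distinct unrooted *binary* topologies
    attaining ``best_length``; ``n_examined`` counts scored partial trees
    (a search-effort diagnostic).  Use :func:`condense_trees` to merge
    trees that differ only in branches never required to carry a change.
    """

    best_length: int
    trees: list[Tree]
    n_examined: int = 0

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def branch_and_bound_search(matrix: CharacterMatrix) -> MPSearchResult:
    """Find the optimal length and *all* optimal unrooted topologies.

    Exact and deterministic: leaf insertion order is the matrix taxon
    order, pruning is strict-inequality only, and no randomization is used,
    so the result set is the set of global optima regardless of input
    order (a property the test suite checks against the enumeration
    oracle).
    """

    n = matrix.n_taxa
    if n < 3:
        raise ValueError("need at least 3 taxa to search")
    if n > SEARCH_CAP:
        raise ValueError(
            f"{n} taxa is beyond the exact-search cap ({SEARCH_CAP}); "
            "a heuristic search is outside this package's scope")

    scorer = _PackedScorer(matrix)

    # Admissible per-level additions to the lower bound: a character that is
    # constant across the first k taxa but variable over all taxa must still
    # change at least once somewhere in any completion.
    states = matrix.states
    variable = [c for c in range(matrix.n_characters)
                if states[:, c].min() != states[:, c].max()]
    extra = []
    for k in range(n + 1):
        count = 0
        for c in variable:
            col = states[:k, c]
            if k == 0 or col.min() == col.max():
                count += 1
        extra.append(count)

    greedy_tree, upper = stepwise_addition_bound(matrix)
    best = upper
    optima: list[_TupleTree] = []
    examined = 0

    def descend(tree: _TupleTree, k: int) -> None:
        nonlocal best, examined, optima
        examined += 1
        length = scorer.length(tree)
        if length + extra[k] > best:
            return
        if k == n:
            if length < best:
                best = length
                optima = []
            if length == best:
                optima.append(tree)
            return
        for bigger in _insertions(tree, k):
            descend(bigger, k + 1)

    descend((0, 1, 2), 3)
    trees = [_tuple_to_tree(t, matrix.taxa) for t in optima]
    return MPSearchResult(best_length=best, trees=trees, n_examined=examined)


# ---------------------------------------------------------------------------
# condensation (collapse branches of maximum length zero)
# ---------------------------------------------------------------------------

def _possible_change_edges(tree: Tree, matrix: CharacterMatrix) -> dict[frozenset, bool]:
    """For each internal edge (keyed by the child-side leaf set), whether any
    character places a change on it in at least one minimal reconstruction.

    Uses inside (Sankoff) and outside dynamic programs per node, so the
    cost is linear in nodes, with no enumeration of reconstructions.
    """

    _require_same_leaves(tree, matrix)
    n_char = matrix.n_characters
    big = np.iinfo(np.int64).max // 4
    taxon_row = {t: i for i, t in enumerate(matrix.taxa)}

    down: dict[int, np.ndarray] = {}
    leafsets: dict[int, frozenset] = {}
    parent: dict[int, Optional[Node]] = {}
    nodes: list[Node] = list(tree.root.postorder())
    ids = {id(nd): nd for nd in nodes}

    for nd in nodes:
        for c in nd.children:
            parent[id(c)] = nd
    parent[id(tree.root)] = None

    for nd in nodes:
        if nd.is_leaf:
            states = matrix.states[taxon_row[nd.label]].astype(np.int64)
            cost = np.full((n_char, 2), big, dtype=np.int64)
            cost[np.arange(n_char), states] = 0
            down[id(nd)] = cost
            leafsets[id(nd)] = frozenset([nd.label])
        else:
            total = np.zeros((n_char, 2), dtype=np.int64)
            for c in nd.children:
                cc = down[id(c)]
                total[:, 0] += np.minimum(cc[:, 0], cc[:, 1] + 1)
                total[:, 1] += np.minimum(cc[:, 1], cc[:, 0] + 1)
            down[id(nd)] = total
            leafsets[id(nd)] = frozenset().union(*(leafsets[id(c)] for c in nd.children))

    overall = down[id(tree.root)].min(axis=1)  # per-character optimum

    # outside DP: A[node][s] = min cost of the whole tree minus subtree(node),
    # with node assigned s (the edge to its parent included).
    A: dict[int, np.ndarray] = {id(tree.root): np.zeros((n_char, 2), dtype=np.int64)}
    out: dict[frozenset, bool] = {}
    for nd in reversed(nodes):  # preorder
        if nd.is_leaf:
            continue
        a_u = A[id(nd)]
        child_msgs = {}
        for c in nd.children:
            cc = down[id(c)]
            msg = np.stack([np.minimum(cc[:, 0], cc[:, 1] + 1),
                            np.minimum(cc[:, 1], cc[:, 0] + 1)], axis=1)
            child_msgs[id(c)] = msg
        total_msg = a_u + sum(child_msgs.values())
        for c in nd.children:
            outc = total_msg - child_msgs[id(c)]  # Out(nd, c)[t], t in {0,1}
            cc = down[id(c)]
            # can edge (nd, c) bear a change in some minimal reconstruction?
            cross = np.minimum(outc[:, 0] + 1 + cc[:, 1],
                               outc[:, 1] + 1 + cc[:, 0])
            changeable = bool(np.any(cross == overall))
            if not c.is_leaf:
                out[leafsets[id(c)]] = changeable
            A[id(c)] = np.stack([np.minimum(outc[:, 0], outc[:, 1] + 1),
                                 np.minimum(outc[:, 1], outc[:, 0] + 1)], axis=1)
    return out


def condense_tree(tree: Tree, matrix: CharacterMatrix) -> Tree:
    """Collapse internal branches whose maximum length is zero.

    A branch has maximum length zero when no character, in any minimal
    reconstruction on this topology, places a change on it; such branches
    are topologically arbitrary among equally parsimonious trees, and
    classic parsimony software collapses them before counting distinct MP
    trees.
    """

    changeable = _possible_change_edges(tree, matrix)

    def rebuild(node: Node) -> list[Node]:
        if node.is_leaf:
            return [Node(label=node.label)]
        kids = []
        for c in node.children:
            kids.extend(rebuild(c))
        if node is tree.root:
            return [Node(children=kids)]
        leafset = frozenset(n.label for k in [node] for n in k.postorder() if n.is_leaf)
        if changeable.get(leafset, True):
            return [Node(children=kids)]
        return kids  # collapse: splice children into the parent

    root = rebuild(tree.root)[0]
    return Tree(root, rooted=tree.rooted)


def condense_trees(trees: Sequence[Tree], matrix: CharacterMatrix) -> list[Tree]:
    """Condense each tree and drop duplicates (bipartition-set equality).

    Order-stable: the first representative of each condensed topology is
    kept in input order.
    """

    seen = set()
    out = []
    for t in trees:
        ct = condense_tree(t, matrix)
        key = (ct.rooted, ct.leaf_labels, ct.splits() if not ct.rooted else ct.clades())
        if key not in seen:
            seen.add(key)
            out.append(ct)
    return out
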