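"""Fitch scoring, tree enumeration, and the exact branch-and-bound search."""

import numpy as np
import pytest

import chromoclad as cc
from chromoclad import (Tree, branch_and_bound_search, condense_trees,
                        enumerate_unrooted_trees, fitch_length,
                        n_unrooted_topologies, stepwise_addition_bound)

from _util import brute_force_length, make_matrix, random_binary_matrix


class TestFitchLength:
    def test_compatible_quartet_needs_one_change(self):
        tree = Tree.from_newick("(A,B,(C,D));")
        mat = make_matrix({"A": "1", "B": "1", "C": "0", "D": "0"})
        assert fitch_length(tree, mat) == 1

    def test_incompatible_quartet_needs_two(self):
        tree = Tree.from_newick("(A,B,(C,D));")
        mat = make_matrix({"A": "1", "B": "0", "C": "1", "D": "0"})
        assert fitch_length(tree, mat) == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        mat = random_binary_matrix(rng, n_taxa=6, n_chars=12)
        for tree in _sample_trees(mat.taxa, rng, k=4):
            assert fitch_length(tree, mat) == brute_force_length(tree, mat)

    def test_invariant_under_rerooting(self, bundled_matrix, bundled_search):
        tree = bundled_search.trees[0]
        unrooted_score = fitch_length(tree, bundled_matrix)
        for og in ("GGA", "BBU", "FTI"):
            rooted = cc.root_at_outgroup(tree, og)
            assert fitch_length(rooted, bundled_matrix) == unrooted_score

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(5)
        mat = random_binary_matrix(rng, n_taxa=6, n_chars=10)
        tree = next(enumerate_unrooted_trees(mat.taxa))
        base = fitch_length(tree, mat)
        perm = list(rng.permutation(mat.taxa))
        relabel = dict(zip(mat.taxa, perm))
        # permute both tree leaves and matrix rows consistently
        renamed = Tree.from_newick(tree.to_newick())
        for node in renamed.root.postorder():
            if node.is_leaf:
                node.label = relabel[node.label]
        renamed = Tree(renamed.root, rooted=False)
        mat2 = make_matrix({relabel[t]: "".join(str(int(s)) for s in mat.states[i])
                            for i, t in enumerate(mat.taxa)})
        assert fitch_length(renamed, mat2) == base

    def test_polytomy_scored_exactly(self):
        star = Tree.from_newick("(A,B,C,D,E);")
        mat = make_matrix({"A": "1", "B": "1", "C": "1", "D": "0", "E": "0"})
        # Sankoff on the star: min(#ones, #zeros + 1 for root flip) = 2
        assert fitch_length(star, mat) == brute_force_length(star, mat) == 2

    def test_leaf_mismatch_lists_difference(self, bundled_matrix):
        tree = Tree.from_newick("(A,B,(C,D));")
        with pytest.raises(ValueError, match="GGA"):
            fitch_length(tree, bundled_matrix)


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(4, 3), (5, 15), (6, 105)])
    def test_topology_counts(self, n, count):
        taxa = [f"t{i}" for i in range(n)]
        trees = list(enumerate_unrooted_trees(taxa))
        assert len(trees) == count == n_unrooted_topologies(n)

    def test_seven_taxa_all_distinct(self):
        taxa = [f"t{i}" for i in range(7)]
        split_sets = {t.splits() for t in enumerate_unrooted_trees(taxa)}
        assert len(split_sets) == 945

    def test_cap_refusal_mentions_branch_and_bound(self):
        taxa = [f"t{i}" for i in range(30)]
        with pytest.raises(ValueError, match="branch_and_bound"):
            list(enumerate_unrooted_trees(taxa))


class TestStepwiseAddition:
    def test_zero_matrix_has_zero_length(self):
        mat = make_matrix({t: "000" for t in "ABCDE"})
        tree, length = stepwise_addition_bound(mat)
        assert length == 0

    def test_self_consistent(self):
        rng = np.random.default_rng(11)
        mat = random_binary_matrix(rng, n_taxa=7, n_chars=15)
        tree, length = stepwise_addition_bound(mat)
        assert fitch_length(tree, mat) == length

    def test_upper_bounds_the_optimum(self):
        rng = np.random.default_rng(12)
        for seed in range(5):
            mat = random_binary_matrix(np.random.default_rng(seed), 6, 14)
            _, greedy = stepwise_addition_bound(mat)
            assert greedy >= branch_and_bound_search(mat).best_length


class TestBranchAndBound:
    @pytest.mark.parametrize("seed", range(6))
    def test_equals_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n_taxa = int(rng.integers(5, 8))
        mat = random_binary_matrix(rng, n_taxa, n_chars=16)
        result = branch_and_bound_search(mat)
        scored = [(fitch_length(t, mat), t) for t in enumerate_unrooted_trees(mat.taxa)]
        best = min(s for s, _ in scored)
        oracle = {t for s, t in scored if s == best}
        assert result.best_length == best
        assert set(result.trees) == oracle

    def test_result_trees_all_optimal_and_distinct(self, bundled_matrix,
                                                   bundled_search):
        lengths = {fitch_length(t, bundled_matrix) for t in bundled_search.trees}
        assert lengths == {bundled_search.best_length}
        assert len({t.splits() for t in bundled_search.trees}) == len(bundled_search.trees)

    def test_insertion_order_does_not_change_the_set(self):
        rng = np.random.default_rng(42)
        mat = random_binary_matrix(rng, 6, 12)
        base = branch_and_bound_search(mat)
        shuffled = list(rng.permutation(mat.taxa))
        mat2 = make_matrix({t: "".join(str(int(s)) for s in mat.states[mat.taxa.index(t)])
                            for t in shuffled})
        other = branch_and_bound_search(mat2)
        assert other.best_length == base.best_length
        assert set(other.trees) == set(base.trees)

    def test_constant_characters_change_nothing(self):
        rng = np.random.default_rng(9)
        mat = random_binary_matrix(rng, 6, 10)
        base = branch_and_bound_search(mat)
        padded = make_matrix({t: "".join(str(int(s)) for s in mat.states[i]) + "01"[0] + "1"
                              for i, t in enumerate(mat.taxa)})
        result = branch_and_bound_search(padded)
        assert result.best_length == base.best_length
        assert set(result.trees) == set(base.trees)

    def test_too_many_taxa_refused(self):
        mat = make_matrix({f"t{i:02d}": "01" for i in range(20)})
        with pytest.raises(ValueError, match="heuristic"):
            branch_and_bound_search(mat)


class TestCondensation:
    def test_unsupported_branch_collapses(self):
        # a single informative character: the resolution of C, D, E is
        # arbitrary, so the three binary MP trees condense to one
        mat = make_matrix({"A": "1", "B": "1", "C": "0", "D": "0", "E": "0"})
        result = branch_and_bound_search(mat)
        condensed = condense_trees(result.trees, mat)
        assert len(result.trees) == 3
        assert len(condensed) == 1
        assert condensed[0].splits() == frozenset({frozenset({"C", "D", "E"})})

    def test_supported_branches_survive(self):
        mat = make_matrix({"A": "00", "B": "01", "C": "01", "D": "10", "E": "10"})
        result = branch_and_bound_search(mat)
        condensed = condense_trees(result.trees, mat)
        for tree in condensed:
            assert frozenset({"B", "C"}) in tree.splits()
            assert frozenset({"D", "E"}) in tree.splits()


def _sample_trees(taxa, rng, k):
    all_trees = list(enumerate_unrooted_trees(taxa))
    idx = rng.choice(len(all_trees), size=min(k, len(all_trees)), replace=False)
    return [all_trees[i] for i in idx]
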