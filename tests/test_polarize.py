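"""Outgroup rooting, minimal-change scenarios, and character classification."""

import itertools

import numpy as np
import pytest

import chromoclad as cc
from chromoclad import (Tree, clade_signature_characters, classify_characters,
                        fitch_length, map_characters_on_topology,
                        minimal_change_placements, root_at_outgroup,
                        summarize_changes)

from _util import brute_force_length, make_matrix


class TestRootAtOutgroup:
    def test_outgroup_becomes_root_child(self):
        t = Tree.from_newick("(a,b,(x,(c,d)));")
        rooted = root_at_outgroup(t, "x")
        assert rooted.rooted
        labels = [c.label for c in rooted.root.children]
        assert "x" in labels

    def test_round_trip_recovers_topology(self):
        t = Tree.from_newick("(a,b,(c,(d,e)));")
        for og in "abcde":
            assert root_at_outgroup(t, og).unrooted() == t

    def test_bundled_tree_has_twelve_ingroup_leaves(self, bundled_search):
        rooted = root_at_outgroup(bundled_search.trees[0], "GGA")
        ingroup = next(c for c in rooted.root.children if c.label != "GGA")
        assert sum(1 for n in ingroup.postorder() if n.is_leaf) == 12

    def test_missing_outgroup(self):
        t = Tree.from_newick("(a,b,(c,d));")
        with pytest.raises(cc.TreeError, match="outgroup"):
            root_at_outgroup(t, "z")


class TestMinimalChangePlacements:
    def test_single_derived_leaf_is_one_pendant_gain(self):
        t = root_at_outgroup(Tree.from_newick("(o,a,(b,(c,d)));"), "o")
        count, scenarios = minimal_change_placements(
            t, {"o": 0, "a": 0, "b": 0, "c": 1, "d": 0}, ancestral_state=0)
        assert count == 1
        assert scenarios == {frozenset({cc.ChangeEvent(frozenset({"c"}), "gain")})}

    def test_constant_character_has_no_events(self):
        t = root_at_outgroup(Tree.from_newick("(o,a,(b,c));"), "o")
        count, scenarios = minimal_change_placements(
            t, {"o": 0, "a": 0, "b": 0, "c": 0}, ancestral_state=0)
        assert count == 0
        assert scenarios == {frozenset()}

    def test_derived_outgroup_polarizes_as_ingroup_loss(self, bundled_matrix,
                                                        bundled_search):
        # the fused chicken chromosome 4 (character 59) is present in GGA
        # only: under outgroup comparison the root state is 1 and the single
        # change is a loss along the ingroup stem
        tree = root_at_outgroup(bundled_search.trees[0], "GGA")
        states = bundled_matrix.character_states(59)
        count, scenarios = minimal_change_placements(tree, states,
                                                     ancestral_state=1)
        assert count == 1
        (scenario,) = scenarios
        (event,) = scenario
        assert event.direction == "loss"
        assert event.clade == frozenset(bundled_matrix.taxa) - {"GGA"}

    def test_root_constraint_never_costs_extra(self):
        rng = np.random.default_rng(3)
        t = root_at_outgroup(Tree.from_newick("(o,a,(b,(c,(d,e))));"), "o")
        leaves = sorted(t.leaf_labels)
        for _ in range(30):
            states = {l: int(rng.integers(2)) for l in leaves}
            free_count, _ = minimal_change_placements(t, states)
            anchored, _ = minimal_change_placements(t, states,
                                                    ancestral_state=states["o"])
            assert anchored == free_count

    def test_gains_and_losses_alternate_along_nested_clades(self):
        rng = np.random.default_rng(8)
        t = root_at_outgroup(Tree.from_newick("(o,(a,b),((c,d),(e,f)));"), "o")
        leaves = sorted(t.leaf_labels)
        for _ in range(40):
            states = {l: int(rng.integers(2)) for l in leaves}
            _, scenarios = minimal_change_placements(t, states,
                                                     ancestral_state=states["o"])
            for scenario in scenarios:
                events = sorted(scenario, key=lambda e: -len(e.clade))
                for e1, e2 in itertools.combinations(events, 2):
                    if e2.clade < e1.clade:
                        between = [e for e in events
                                   if e2.clade < e.clade < e1.clade]
                        if not between:
                            assert e1.direction != e2.direction


class TestClassification:
    def test_clean_synapomorphy_is_unambiguous(self):
        mat = make_matrix({"O": "0", "A": "0", "B": "1", "C": "1"})
        tree = Tree.from_newick("(O,A,(B,C));")
        (verdict,) = classify_characters(mat, [tree])
        assert verdict.verdict == "unambiguous"
        assert verdict.supporting_clade == frozenset({"B", "C"})

    def test_verdicts_partition_character_set(self, bundled_matrix,
                                              bundled_condensed):
        verdicts = classify_characters(bundled_matrix, bundled_condensed)
        tally = summarize_changes(verdicts)
        assert tally.total == bundled_matrix.n_characters

    def test_verdicts_invariant_to_tree_order(self, bundled_matrix,
                                              bundled_condensed):
        rng = np.random.default_rng(1)
        shuffled = list(bundled_condensed)
        rng.shuffle(shuffled)
        a = classify_characters(bundled_matrix, bundled_condensed)
        b = classify_characters(bundled_matrix, shuffled)
        assert [v.verdict for v in a] == [v.verdict for v in b]

    def test_empty_summary_is_zero(self):
        tally = summarize_changes([])
        assert (tally.unambiguous, tally.homoplastic, tally.ambiguous) == (0, 0, 0)

    def test_mptrees_mode_requires_per_tree_agreement(self):
        # one tree reads the character as a synapomorphy of {B,C}, the other
        # cannot: the strict per-tree rule must not call it unambiguous
        mat = make_matrix({"O": "0", "A": "0", "B": "1", "C": "1", "D": "0"})
        t1 = Tree.from_newick("(O,A,(D,(B,C)));")
        t2 = Tree.from_newick("(O,A,(B,(D,C)));")
        (v,) = classify_characters(mat, [t1, t2], mode="mptrees")
        assert v.verdict == "ambiguous"


class TestCladeSignatures:
    def test_exact_match_only(self):
        mat = make_matrix({"O": "00", "A": "10", "B": "11", "C": "01"})
        assert clade_signature_characters(mat, {"B", "C"}) == [2]
        assert clade_signature_characters(mat, {"A", "B"}) == [1]
        assert clade_signature_characters(mat, {"A", "C"}) == []

    def test_empty_set_matches_allzero_characters_only(self, bundled_matrix):
        assert clade_signature_characters(bundled_matrix, frozenset()) == []

    def test_unknown_taxon_rejected(self, bundled_matrix):
        with pytest.raises(KeyError, match="XYZ"):
            clade_signature_characters(bundled_matrix, {"XYZ"})


class TestMapOnTopology:
    def test_star_tree_counts_every_derived_taxon(self):
        # on a star, each derived taxon needs its own gain (as long as the
        # derived taxa are the minority, flipping the hub costs more)
        mat = make_matrix({"O": "0", "A": "1", "B": "1", "C": "0", "D": "0",
                           "E": "0"})
        star = Tree.from_newick("(O,A,B,C,D,E);")
        (placement,) = map_characters_on_topology(mat, star)
        assert placement.min_changes == 2
        assert placement.homoplastic_on_tree

    def test_all_zero_character_maps_nowhere(self):
        mat = make_matrix({"O": "0", "A": "0", "B": "0", "C": "0"})
        (placement,) = map_characters_on_topology(
            mat, Tree.from_newick("(O,A,(B,C));"))
        assert placement.min_changes == 0
        assert placement.change_edges == frozenset()

    def test_per_character_counts_sum_to_fitch_length(self, bundled_matrix,
                                                      bundled_search):
        tree = bundled_search.trees[0]
        placements = map_characters_on_topology(bundled_matrix, tree)
        assert (sum(p.min_changes for p in placements)
                == fitch_length(tree, bundled_matrix))

    def test_polytomy_counts_match_assignment_enumeration(self):
        mat = make_matrix({"O": "01", "A": "11", "B": "10", "C": "01", "D": "11"})
        poly = Tree.from_newick("(O,A,(B,C,D));")
        placements = map_characters_on_topology(mat, poly)
        rooted = root_at_outgroup(poly, "O")
        assert (sum(p.min_changes for p in placements)
                == brute_force_length(rooted, mat))

    def test_leaf_mismatch_rejected(self, bundled_matrix):
        with pytest.raises(ValueError, match="differ"):
            map_characters_on_topology(bundled_matrix,
                                       Tree.from_newick("(GGA,FTI,(FPE,FCO));"))
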