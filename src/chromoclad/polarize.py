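"""Outgroup polarization, change placement and character classification.

Maximum parsimony only counts changes; to say *what happened* each
character's changes must be polarized — assigned a direction (gain of the
derived rearrangement, 0→1, or loss/reversal, 1→0) — and placed on
branches.  The outgroup comparison criterion does this a posteriori: the
tree is rooted on the outgroup's pendant edge and the state observed in
the outgroup is taken as ancestral at the root.  All ancestral-state
assignments attaining the Fitch minimum are then enumerated; each distinct
set of (branch, direction) events is a *minimal scenario* for that
character.

A character with a single, stable minimal scenario is interpretable: if
the scenario is one gain it is a clean synapomorphy of the clade below
the gain branch; a unique multi-event scenario still tells a definite
story (e.g. a basal gain followed by one reversal).  Interpretation breaks
down in two ways, and the classifier distinguishes them:

* the character needs two or more changes on the consensus and on (almost)
  every equally parsimonious tree — the homoplasy is real, but whether it
  is two convergent gains or a gain plus a reversal can flip with the
  resolution of unstable branches ("homoplastic", i.e.
  convergent-or-reversal);
* the character's minimal change count itself depends on how the unstable
  taxa branch: on an appreciable fraction of the MP trees it is a clean
  single-gain synapomorphy, on the rest it is homoplastic — it cannot be
  read at all against the topological uncertainty ("ambiguous"; likewise
  when the consensus admits several minimal scenarios).

The boundary between those two is ``instability_tolerance`` (default 0.2):
a consensus-homoplastic character that is a clean synapomorphy on at most
that fraction of the MP trees keeps its homoplastic reading; beyond it the
character is declared ambiguous.  A character homoplastic on *every* MP
tree with a unique consensus scenario stays unambiguous — its story (e.g.
a basal gain with one terminal reversal) is the same everywhere.  See the
methods note for the rationale; the stricter per-tree rule used by some
workers is available as ``mode="mptrees"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from .characters import CharacterDef, CharacterMatrix
from .consensus import majority_rule_consensus
from .trees import Node, Tree, TreeError

Direction = Literal["gain", "loss"]
Verdict = Literal["unambiguous", "homoplastic", "ambiguous"]


@dataclass(frozen=True, order=True)
class ChangeEvent:
    """A polarized state change on one branch.

    The branch is identified by the leaf set below it (child side) —
    stable across trees, unlike node identities.  ``direction`` is "gain"
    (0→1) or "loss" (1→0).
    """

    clade: frozenset[str]
    direction: Direction

    def __repr__(self) -> str:
        return f"{self.direction}({'+'.join(sorted(self.clade))})"


Scenario = frozenset  # of ChangeEvent


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def root_at_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Root a tree on the outgroup's pendant edge.

    The returned tree is rooted, with the outgroup leaf as one child of the
    root and the entire ingroup as the other; ingroup substructure
    (including polytomies) is unchanged.
    """

    if outgroup not in tree.leaf_labels:
        raise TreeError(f"outgroup {outgroup!r} is not a leaf of the tree")
    base = tree.unrooted() if tree.rooted else tree.copy()
    if tree.n_leaves < 3:
        raise TreeError("rooting needs at least 3 leaves")

    parent: dict[int, Optional[Node]] = {id(base.root): None}
    for node in base.root.postorder():
        for c in node.children:
            parent[id(c)] = node

    og = next(n for n in base.root.postorder() if n.is_leaf and n.label == outgroup)

    def hang(node: Node, away_from: Node) -> Node:
        """Re-orient the unrooted tree: subtree at ``node`` looking away from
        ``away_from``."""
        kids = [c for c in node.children if c is not away_from]
        p = parent[id(node)]
        if p is not None and p is not away_from:
            kids.append(hang(p, node))
        if not kids:  # node is a leaf seen from its neighbour
            return Node(label=node.label)
        if len(kids) == 1:
            return kids[0]  # suppress the degree-2 node left by re-rooting
        return Node(children=kids)

    ingroup = hang(parent[id(og)], og)
    return Tree(Node(children=[Node(label=outgroup), ingroup]), rooted=True)


# ---------------------------------------------------------------------------
# minimal-change scenarios for one character
# ---------------------------------------------------------------------------

_BIG = 10 ** 9


def minimal_change_placements(rooted_tree: Tree,
                              character_states: dict[str, int],
                              ancestral_state: Optional[int] = None,
                              ) -> tuple[int, frozenset[Scenario]]:
    """All minimal-change placements of one binary character.

    Enumerates every ancestral-state assignment attaining the parsimony
    minimum (unit-cost Sankoff, exact on polytomies) and summarizes each as
    its set of :class:`ChangeEvent`.  If ``ancestral_state`` is given the
    root is constrained to it — the outgroup comparison criterion; the
    constraint never costs extra steps when the root is adjacent to the
    outgroup leaf.  Returns ``(min_changes, scenarios)``.
    """

    if not rooted_tree.rooted:
        raise TreeError("minimal_change_placements expects a rooted tree")
    missing = rooted_tree.leaf_labels - set(character_states)
    if missing:
        raise ValueError(f"no state for leaves {sorted(missing)}")

    cost: dict[int, list[int]] = {}
    leafset: dict[int, frozenset[str]] = {}

    for node in rooted_tree.root.postorder():
        if node.is_leaf:
            s = character_states[node.label]
            if s not in (0, 1):
                raise ValueError(f"state of {node.label!r} must be 0/1, got {s!r}")
            cost[id(node)] = [0 if s == 0 else _BIG, 0 if s == 1 else _BIG]
            leafset[id(node)] = frozenset([node.label])
        else:
            c0 = c1 = 0
            for child in node.children:
                cc = cost[id(child)]
                c0 += min(cc[0], cc[1] + 1)
                c1 += min(cc[1], cc[0] + 1)
            cost[id(node)] = [c0, c1]
            leafset[id(node)] = frozenset().union(*(leafset[id(c)] for c in node.children))

    root_cost = cost[id(rooted_tree.root)]
    if ancestral_state is None:
        minimum = min(root_cost)
        root_states = [s for s in (0, 1) if root_cost[s] == minimum]
    else:
        if ancestral_state not in (0, 1):
            raise ValueError("ancestral_state must be 0 or 1")
        minimum = root_cost[ancestral_state]
        root_states = [ancestral_state]

    def expand(node: Node, state: int, events: frozenset) -> list[frozenset]:
        outs = [events]
        for child in node.children:
            cc = cost[id(child)]
            keep, flip = cc[state], cc[1 - state] + 1
            options = []
            if keep <= flip:
                options.append((state, None))
            if flip <= keep:
                direction: Direction = "gain" if state == 0 else "loss"
                options.append((1 - state, ChangeEvent(leafset[id(child)], direction)))
            new_outs = []
            for ev in outs:
                for child_state, event in options:
                    ev2 = ev | {event} if event else ev
                    new_outs.extend(expand(child, child_state, ev2))
            outs = new_outs
        return outs

    scenarios = set()
    for rs in root_states:
        for ev in expand(rooted_tree.root, rs, frozenset()):
            scenarios.add(Scenario(ev))
    return minimum, frozenset(scenarios)


# ---------------------------------------------------------------------------
# classification over a set of MP trees
# ---------------------------------------------------------------------------

@dataclass
class CharacterClassification:
    """Verdict for one character over a set of equally parsimonious trees."""

    character: CharacterDef
    verdict: Verdict
    per_tree_changes: list[int]
    consensus_changes: Optional[int] = None
    consensus_scenarios: frozenset = frozenset()
    supporting_clade: Optional[frozenset[str]] = None

    @property
    def index(self) -> int:
        return self.character.index

    @property
    def rclass(self) -> str:
        return self.character.rclass


def _trace(tree_rooted: Tree, matrix: CharacterMatrix, char_index: int):
    states = matrix.character_states(char_index)
    ancestral = states[matrix.outgroup]
    return minimal_change_placements(tree_rooted, states, ancestral_state=ancestral)


def classify_characters(matrix: CharacterMatrix,
                        mp_trees: Sequence[Tree],
                        mode: Literal["consensus", "mptrees"] = "consensus",
                        consensus: Optional[Tree] = None,
                        instability_tolerance: float = 0.2,
                        ) -> list[CharacterClassification]:
    """Classify every character as unambiguous / homoplastic / ambiguous.

    ``mode="consensus"`` (default) polarizes on the 50% majority-rule tree
    of ``mp_trees`` (or a supplied ``consensus``) and checks the stability
    of the reading across the MP trees, as described in the module
    docstring.  ``mode="mptrees"`` applies the stricter per-tree rule: a
    character is unambiguous only if it shows the same unique single-change
    scenario on every MP tree, homoplastic only if it needs >= 2 changes on
    every MP tree, and ambiguous otherwise.
    """

    if not mp_trees:
        raise ValueError("need at least one most-parsimonious tree")
    rooted = [root_at_outgroup(t, matrix.outgroup) for t in mp_trees]
    if mode == "consensus":
        cons = consensus if consensus is not None else majority_rule_consensus(
            [t.unrooted() if t.rooted else t for t in mp_trees])
        cons_rooted = root_at_outgroup(cons, matrix.outgroup)
    elif mode == "mptrees":
        cons_rooted = None
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out: list[CharacterClassification] = []
    for char in matrix.characters:
        traces = [_trace(rt, matrix, char.index) for rt in rooted]
        counts = [t[0] for t in traces]
        scen_sets = [t[1] for t in traces]

        if mode == "mptrees":
            verdict, clade = _verdict_per_tree(counts, scen_sets)
            out.append(CharacterClassification(
                character=char, verdict=verdict, per_tree_changes=counts,
                supporting_clade=clade))
            continue

        c_count, c_scens = _trace(cons_rooted, matrix, char.index)
        if len(c_scens) != 1:
            verdict, clade = "ambiguous", None
        else:
            scenario = next(iter(c_scens))
            if c_count <= 1:
                verdict = "unambiguous"
                clade = next(iter(scenario)).clade if scenario else None
            else:
                # The character is homoplastic on the consensus.  Is the
                # homoplasy itself certain?  Count the MP trees on which it
                # would instead be a clean synapomorphy (or constant).
                dissenting = sum(1 for c in counts if c <= 1)
                frac = dissenting / len(counts)
                if dissenting == 0:
                    verdict = "unambiguous"
                    gains = [e for e in scenario if e.direction == "gain"]
                    clade = max((e.clade for e in gains), key=len, default=None)
                elif frac <= instability_tolerance:
                    verdict, clade = "homoplastic", None
                else:
                    verdict, clade = "ambiguous", None
        out.append(CharacterClassification(
            character=char, verdict=verdict, per_tree_changes=counts,
            consensus_changes=c_count, consensus_scenarios=c_scens,
            supporting_clade=clade))
    return out


def _verdict_per_tree(counts: list[int], scen_sets: list[frozenset]
                      ) -> tuple[Verdict, Optional[frozenset]]:
    if counts and all(c >= 2 for c in counts):
        return "homoplastic", None
    if all(c == 0 for c in counts):
        return "unambiguous", None
    if (all(c == 1 for c in counts)
            and all(len(s) == 1 for s in scen_sets)
            and len(set(scen_sets)) == 1):
        only_scenario = next(iter(scen_sets[0]))
        event = next(iter(only_scenario))
        return "unambiguous", event.clade
    return "ambiguous", None


@dataclass(frozen=True)
class ChangeSummary:
    """Tally of verdicts, with the unambiguous class split by rclass."""

    unambiguous_associations: int = 0
    unambiguous_disruptions: int = 0
    homoplastic: int = 0
    ambiguous: int = 0

    @property
    def unambiguous(self) -> int:
        return self.unambiguous_associations + self.unambiguous_disruptions

    @property
    def total(self) -> int:
        return self.unambiguous + self.homoplastic + self.ambiguous


def summarize_changes(classifications: Sequence[CharacterClassification]
                      ) -> ChangeSummary:
    ua = ud = h = a = 0
    for cl in classifications:
        if cl.verdict == "unambiguous":
            if cl.rclass == "association":
                ua += 1
            else:
                ud += 1
        elif cl.verdict == "homoplastic":
            h += 1
        else:
            a += 1
    return ChangeSummary(ua, ud, h, a)


# ---------------------------------------------------------------------------
# clade signatures and mapping on a fixed topology
# ---------------------------------------------------------------------------

def clade_signature_characters(matrix: CharacterMatrix,
                               clade_leafset: Sequence[str] | frozenset[str]
                               ) -> list[int]:
    """Characters whose derived (state 1) taxa are exactly the given set.

    These are the potential synapomorphies of that clade: a single gain on
    the clade's stem explains each of them.
    """

    target = frozenset(clade_leafset)
    unknown = target - set(matrix.taxa)
    if unknown:
        raise KeyError(f"unknown taxa in clade: {sorted(unknown)}")
    return [c.index for c in matrix.characters
            if matrix.derived_taxa(c.index) == target]


@dataclass
class CharacterPlacement:
    """Minimal placements of one character on a fixed topology."""

    character: CharacterDef
    min_changes: int
    scenarios: frozenset
    homoplastic_on_tree: bool

    @property
    def change_edges(self) -> frozenset[frozenset[str]]:
        """Union over scenarios of the clades below changed branches."""
        return frozenset(e.clade for sc in self.scenarios for e in sc)


def map_characters_on_topology(matrix: CharacterMatrix,
                               fixed_tree: Tree,
                               outgroup: Optional[str] = None,
                               ) -> list[CharacterPlacement]:
    """Trace every character on an independently obtained topology.

    The tree may be multifurcating (e.g. a consensus of molecular trees);
    counts are exact minima over ancestral states.  The tree is re-rooted
    on the outgroup and changes are polarized by the outgroup criterion.
    Characters needing >= 2 changes are flagged homoplastic on this
    topology.
    """

    og = outgroup or matrix.outgroup
    rooted = root_at_outgroup(fixed_tree, og)
    if rooted.leaf_labels != frozenset(matrix.taxa):
        missing = sorted(frozenset(matrix.taxa) - rooted.leaf_labels)
        extra = sorted(rooted.leaf_labels - frozenset(matrix.taxa))
        raise ValueError(
            f"tree leaves and matrix taxa differ: missing from tree {missing}, "
            f"not in matrix {extra}")
    out = []
    for char in matrix.characters:
        count, scens = _trace(rooted, matrix, char.index)
        out.append(CharacterPlacement(
            character=char, min_changes=count, scenarios=scens,
            homoplastic_on_tree=count >= 2))
    return out
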