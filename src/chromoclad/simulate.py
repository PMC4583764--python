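"""Synthetic trees and rearrangement-like binary characters.

The generator emulates the statistical structure of chromosomal
rearrangement data: rare, mostly irreversible presence/absence characters
arising on a phylogeny, with occasional parallel gains or reversals
producing homoplasy.  An ingroup genealogy is drawn from a Yule
(pure-birth) process; an outgroup leaf is attached at the ingroup root,
mirroring the single-outgroup design of chromosome-painting studies.  Each
character then evolves independently down the tree as a two-state Markov
process from root state 0 (the ancestral karyotype lacks every derived
rearrangement), gaining at ``gain_rate`` and reverting at ``loss_rate``
per unit branch length.

Every simulated character carries its true event log (branch + direction),
so pipeline stages can be checked against a known ground truth.  A
*conditioned* mode plants exactly one gain per character: the first
characters cover each internal branch of the ingroup once (so the
generating topology is identifiable whenever ``n_chars`` is at least the
number of internal branches), and the remainder fall on branches chosen
with probability proportional to branch length.  In that regime every
character is a clean synapomorphy and an exact parsimony search provably
recovers the generating topology.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``, so identical configurations give
bit-identical output, and replicate experiments are reproducible
piecewise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

from .characters import CharacterDef, CharacterMatrix
from .consensus import robinson_foulds, strict_consensus
from .parsimony import branch_and_bound_search, fitch_length
from .polarize import ChangeEvent
from .trees import Node, Tree

OUTGROUP_LABEL = "OUT"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation.

    ``gain_rate``/``loss_rate`` are events per unit branch length; the Yule
    ingroup has unit birth rate, so branch lengths are in units of expected
    waiting time between splits at the root.  ``conditioned`` switches to
    the one-gain-per-character regime (rates are then ignored for the
    planted gain; no losses occur).
    """

    n_taxa: int = 12
    n_chars: int = 59
    gain_rate: float = 0.3
    loss_rate: float = 0.03
    tree_model: Literal["yule", "fixed"] = "yule"
    seed: int = 0
    conditioned: bool = False
    outgroup_branch: float = 1.0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.n_chars < 1:
            raise ValueError("n_chars must be >= 1")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")


def simulate_tree(config: SimulationConfig) -> Tree:
    """A rooted Yule tree with ``n_taxa`` ingroup leaves plus the outgroup.

    Leaf labels are ``T01``..; the outgroup leaf ``OUT`` hangs off the root
    with branch length ``outgroup_branch``.
    """

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_taxa
    t = 0.0
    root_kids = [Node(length=0.0), Node(length=0.0)]
    birth = {id(root_kids[0]): 0.0, id(root_kids[1]): 0.0}
    tips = list(root_kids)
    while len(tips) < n:
        t += rng.exponential(1.0 / len(tips))
        victim = tips[rng.integers(len(tips))]
        victim.length = t - birth[id(victim)]
        kids = [Node(length=0.0), Node(length=0.0)]
        for k in kids:
            birth[id(k)] = t
        victim.children = kids
        tips.remove(victim)
        tips.extend(kids)
    t += rng.exponential(1.0 / len(tips))  # grace period: no zero tip branches
    for i, tip in enumerate(tips):
        tip.length = t - birth[id(tip)]
        tip.label = f"T{i + 1:02d}"
    # both root-incident edges get the configured outgroup branch length
    ingroup = Node(children=root_kids, length=config.outgroup_branch)
    root = Node(children=[Node(label=OUTGROUP_LABEL, length=config.outgroup_branch),
                          ingroup])
    return Tree(root, rooted=True)


@dataclass
class SimulatedCharacter:
    """Ground truth for one character: its true events, in time order."""

    events: list[ChangeEvent] = field(default_factory=list)


def _edges(tree: Tree) -> list[tuple[Node, frozenset[str], float]]:
    """(child node, clade below, branch length) for every non-root edge."""
    leafset: dict[int, frozenset[str]] = {}
    out = []
    for node in tree.root.postorder():
        if node.is_leaf:
            leafset[id(node)] = frozenset([node.label])
        else:
            leafset[id(node)] = frozenset().union(*(leafset[id(c)] for c in node.children))
        if node is not tree.root:
            out.append((node, leafset[id(node)], node.length or 0.0))
    return out


def simulate_matrix(tree: Tree, config: SimulationConfig
                    ) -> tuple[CharacterMatrix, list[SimulatedCharacter]]:
    """Evolve ``n_chars`` binary characters on ``tree``; return the matrix
    and the per-character true event log."""

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    taxa = [OUTGROUP_LABEL] + sorted(tree.leaf_labels - {OUTGROUP_LABEL})
    logs: list[SimulatedCharacter] = []
    columns: list[dict[str, int]] = []

    if config.conditioned:
        edges = [(nd, clade, ln) for nd, clade, ln in _edges(tree)
                 if OUTGROUP_LABEL not in clade]
        internal = [(nd, clade, ln) for nd, clade, ln in edges if len(clade) > 1]
        lengths = np.array([ln for _, _, ln in edges])
        weights = lengths / lengths.sum() if lengths.sum() > 0 else None
        for c in range(config.n_chars):
            if c < len(internal):
                _, clade, _ = internal[c]
            else:
                pick = rng.choice(len(edges), p=weights)
                _, clade, _ = edges[pick]
            logs.append(SimulatedCharacter([ChangeEvent(clade, "gain")]))
            columns.append({t: int(t in clade) for t in taxa})
    else:
        rates = (config.gain_rate, config.loss_rate)
        for _ in range(config.n_chars):
            log = SimulatedCharacter()
            states: dict[str, int] = {}

            def walk(node: Node, state: int, clade_of: dict) -> None:
                for child in node.children:
                    s = state
                    remaining = child.length or 0.0
                    while True:
                        rate = rates[s]
                        if rate <= 0:
                            break
                        wait = rng.exponential(1.0 / rate)
                        if wait >= remaining:
                            break
                        remaining -= wait
                        s = 1 - s
                        log.events.append(
                            ChangeEvent(clade_of[id(child)],
                                        "gain" if s == 1 else "loss"))
                    if child.is_leaf:
                        states[child.label] = s
                    else:
                        walk(child, s, clade_of)

            clade_of = {id(nd): clade for nd, clade, _ in _edges(tree)}
            walk(tree.root, 0, clade_of)
            logs.append(log)
            columns.append(states)

    grid = np.array([[columns[c][t] for c in range(config.n_chars)] for t in taxa],
                    dtype=np.uint8)
    chars = [CharacterDef(i + 1, f"sim{i + 1}", "association") for i in range(config.n_chars)]
    matrix = CharacterMatrix(taxa=taxa, characters=chars, states=grid,
                             outgroup=OUTGROUP_LABEL)
    return matrix, logs


@dataclass(frozen=True)
class RecoverySummary:
    """Aggregate outcome of repeated simulate-and-reestimate experiments."""

    n_replicates: int
    fraction_true_topology: Optional[float] = None
    mean_rf_distance: Optional[float] = None
    mean_excess_length: Optional[float] = None


def recovery_experiment(config: SimulationConfig, n_replicates: int
                        ) -> RecoverySummary:
    """Simulate, search, and compare against the generating topology.

    Per replicate: draw a tree and matrix (seeds derived from the master
    seed), run the exact search, take the strict consensus of all MP trees,
    and measure its Robinson-Foulds distance to the true (unrooted)
    topology.  ``fraction_true_topology`` is the fraction of replicates
    with distance zero; ``mean_excess_length`` is the mean of
    ``fitch_length(true topology) - best_length`` (how much shorter the MP
    trees are than the truth; zero when the truth is itself optimal).
    """

    if n_replicates < 0:
        raise ValueError("n_replicates must be >= 0")
    if n_replicates == 0:
        return RecoverySummary(n_replicates=0)
    rf_values, excess_values, hits = [], [], 0
    for rep in range(n_replicates):
        sub = replace(config, seed=int(np.random.SeedSequence(
            [config.seed, 3, rep]).generate_state(1)[0] % (2 ** 31)))
        tree = simulate_tree(sub)
        matrix, _ = simulate_matrix(tree, sub)
        result = branch_and_bound_search(matrix)
        estimate = strict_consensus(result.trees)
        truth = tree.unrooted()
        rf = robinson_foulds(estimate, truth)
        rf_values.append(rf)
        hits += rf == 0
        excess_values.append(fitch_length(truth, matrix) - result.best_length)
    return RecoverySummary(
        n_replicates=n_replicates,
        fraction_true_topology=hits / n_replicates,
        mean_rf_distance=float(np.mean(rf_values)),
        mean_excess_length=float(np.mean(excess_values)),
    )
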