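"""Shared test helpers: small-matrix builders and brute-force oracles.

The oracles here deliberately avoid the package's dynamic programs: the
parsimony oracle enumerates every ancestral-state assignment explicitly,
so it can disagree with a buggy Fitch/Sankoff implementation.
"""

from __future__ import annotations

import itertools

import numpy as np

from chromoclad import CharacterDef, CharacterMatrix, Tree


def make_matrix(columns: dict[str, str], outgroup: str | None = None,
                rclasses: list[str] | None = None) -> CharacterMatrix:
    """Build a matrix from per-taxon state strings, e.g. {"A": "010", ...}."""
    taxa = list(columns)
    n_chars = len(next(iter(columns.values())))
    chars = [CharacterDef(i + 1, f"c{i + 1}",
                          rclasses[i] if rclasses else "association")
             for i in range(n_chars)]
    grid = np.array([[int(s) for s in columns[t]] for t in taxa], dtype=np.uint8)
    return CharacterMatrix(taxa=taxa, characters=chars, states=grid,
                           outgroup=outgroup or taxa[0])


def random_binary_matrix(rng: np.random.Generator, n_taxa: int,
                         n_chars: int) -> CharacterMatrix:
    """Random 0/1 matrix; columns resampled until non-constant so every
    character is variable (constant characters are separately tested)."""
    cols = []
    while len(cols) < n_chars:
        col = rng.integers(0, 2, size=n_taxa)
        if col.min() != col.max():
            cols.append(col)
    grid = np.array(cols).T.astype(np.uint8)
    taxa = [f"t{i}" for i in range(n_taxa)]
    chars = [CharacterDef(i + 1, f"c{i + 1}", "association") for i in range(n_chars)]
    return CharacterMatrix(taxa=taxa, characters=chars, states=grid, outgroup=taxa[0])


def brute_force_length(tree: Tree, matrix: CharacterMatrix) -> int:
    """Minimum changes by explicit enumeration of all ancestral assignments."""
    nodes = list(tree.root.postorder())
    parent = {}
    for nd in nodes:
        for c in nd.children:
            parent[id(c)] = nd
    internals = [nd for nd in nodes if not nd.is_leaf]
    row = {t: i for i, t in enumerate(matrix.taxa)}
    total = 0
    for j in range(matrix.n_characters):
        best = None
        leaf_state = {id(nd): int(matrix.states[row[nd.label], j])
                      for nd in nodes if nd.is_leaf}
        for bits in itertools.product((0, 1), repeat=len(internals)):
            state = dict(leaf_state)
            for nd, b in zip(internals, bits):
                state[id(nd)] = b
            changes = sum(1 for nd in nodes if id(nd) in parent
                          and state[id(nd)] != state[id(parent[id(nd)])])
            best = changes if best is None else min(best, changes)
        total += best
    return total


def caterpillar(labels: list[str]) -> Tree:
    """A fixed pectinate unrooted tree over the labels (deterministic)."""
    newick = labels[0] + "," + labels[1] + ","
    inner = labels[-1]
    for lab in reversed(labels[2:-1]):
        inner = f"({lab},{inner})"
    return Tree.from_newick(f"({newick}{inner});", rooted=False)
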