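"""End-to-end analysis: search -> condense -> consensus -> polarize -> tally.

This is the chain a chromosome-based cladistic study runs: find every
most-parsimonious tree for the rearrangement matrix, condense trees that
differ only in branches never required to change, summarize them with the
50% majority-rule consensus, polarize each character's changes against the
outgroup, and classify characters as unambiguous synapomorphies,
convergent/reversal events, or uninterpretable against the topological
uncertainty.

The run is fully deterministic: re-running on the same input reproduces
every field of the report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

from . import __version__ as _version
from .characters import CharacterMatrix, load_bundled_matrix, parse_matrix, write_matrix
from .consensus import majority_rule_consensus, polytomy_taxa, strict_consensus
from .parsimony import MPSearchResult, branch_and_bound_search, condense_trees
from .polarize import (CharacterClassification, ChangeSummary,
                       classify_characters, summarize_changes)
from .trees import Tree


@dataclass
class RunReport:
    """Machine-readable record of one full analysis."""

    matrix_digest: str
    n_taxa: int
    n_characters: int
    outgroup: str
    best_length: int
    n_binary_mp_trees: int
    n_mp_trees: int
    n_examined: int
    consensus_newick: str
    strict_consensus_newick: str
    polytomy_taxa: list[str]
    tally: ChangeSummary
    verdicts: list[CharacterClassification]
    classify_mode: str
    version: str = _version

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "matrix_digest": self.matrix_digest,
            "n_taxa": self.n_taxa,
            "n_characters": self.n_characters,
            "outgroup": self.outgroup,
            "best_length": self.best_length,
            "n_binary_mp_trees": self.n_binary_mp_trees,
            "n_mp_trees": self.n_mp_trees,
            "n_examined": self.n_examined,
            "consensus_newick": self.consensus_newick,
            "strict_consensus_newick": self.strict_consensus_newick,
            "polytomy_taxa": sorted(self.polytomy_taxa),
            "classify_mode": self.classify_mode,
            "tally": {
                "unambiguous_associations": self.tally.unambiguous_associations,
                "unambiguous_disruptions": self.tally.unambiguous_disruptions,
                "unambiguous": self.tally.unambiguous,
                "homoplastic": self.tally.homoplastic,
                "ambiguous": self.tally.ambiguous,
            },
            "characters": [
                {
                    "index": v.index,
                    "label": v.character.label,
                    "rclass": v.rclass,
                    "verdict": v.verdict,
                    "per_tree_changes": v.per_tree_changes,
                    "consensus_changes": v.consensus_changes,
                    "supporting_clade": sorted(v.supporting_clade) if v.supporting_clade else None,
                    "scenarios": [
                        sorted(f"{e.direction}:{'+'.join(sorted(e.clade))}" for e in sc)
                        for sc in sorted(v.consensus_scenarios, key=lambda s: sorted(map(repr, s)))
                    ],
                }
                for v in self.verdicts
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def run_full_analysis(matrix: CharacterMatrix | str | Path = "bundled",
                      outgroup: Optional[str] = None,
                      majority_threshold: float = 0.5,
                      classify_mode: Literal["consensus", "mptrees"] = "consensus",
                      out_dir: Optional[str | Path] = None,
                      ) -> RunReport:
    """Run the full chain and optionally write artefacts to ``out_dir``.

    ``matrix`` may be a :class:`CharacterMatrix`, the string ``"bundled"``,
    or a path to a NEXUS/TSV file.  Artefacts written: ``mp_trees.nwk``
    (condensed MP trees), ``mp_trees_binary.nwk``, ``consensus.nwk`` and
    ``report.json``.
    """

    if isinstance(matrix, CharacterMatrix):
        mat = matrix
    elif matrix == "bundled":
        mat = load_bundled_matrix()
    else:
        path = Path(matrix)
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".txt") else "nexus"
        mat = parse_matrix(path.read_text(), dialect=dialect)
    if outgroup is not None:
        if outgroup not in mat.taxa:
            raise ValueError(f"outgroup {outgroup!r} is not a taxon of the matrix")
        mat.outgroup = outgroup

    digest = hashlib.sha256(write_matrix(mat, "tsv").encode()).hexdigest()

    result: MPSearchResult = branch_and_bound_search(mat)
    condensed = condense_trees(result.trees, mat)
    consensus = majority_rule_consensus(condensed, threshold=majority_threshold)
    strict = strict_consensus(condensed)
    verdicts = classify_characters(mat, condensed, mode=classify_mode,
                                   consensus=consensus)
    tally = summarize_changes(verdicts)

    report = RunReport(
        matrix_digest=digest,
        n_taxa=mat.n_taxa,
        n_characters=mat.n_characters,
        outgroup=mat.outgroup,
        best_length=result.best_length,
        n_binary_mp_trees=len(result.trees),
        n_mp_trees=len(condensed),
        n_examined=result.n_examined,
        consensus_newick=consensus.to_newick(),
        strict_consensus_newick=strict.to_newick(),
        polytomy_taxa=sorted(polytomy_taxa(consensus)),
        tally=tally,
        verdicts=verdicts,
        classify_mode=classify_mode,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "mp_trees.nwk").write_text(
            "\n".join(t.to_newick() for t in condensed) + "\n")
        (out / "mp_trees_binary.nwk").write_text(
            "\n".join(t.to_newick() for t in result.trees) + "\n")
        (out / "consensus.nwk").write_text(consensus.to_newick() + "\n")
        (out / "report.json").write_text(report.to_json() + "\n")
    return report
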