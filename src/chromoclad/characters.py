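"""Binary chromosomal-rearrangement character matrices.

The unit of data in a chromosome-based cladistic analysis is a binary
character: the presence (1) or absence (0) of a particular syntenic
*association* (a derived fusion joining segments that are separate in the
reference karyotype) or syntenic *disruption* (a derived fission splitting
a region that is contiguous in the reference karyotype).  Characters are
named by the chicken (GGA) chromosome segments involved, e.g. ``1p/1q`` is
the fission separating the two arms of GGA 1, and ``5qprx/mic1`` is the
fusion of proximal GGA 5q with a microchromosome.

The package bundles the published matrix for the diurnal birds of prey:
59 characters scored over 13 operational taxonomic units (OTUs), with the
chicken as the only outgroup.  OTUs whose painting patterns are identical
are pooled under the first species' abbreviation (GCA = GCA+CAU,
GFU = GFU+GHI+GRU, BNI = BNI+BME+RMA).

Matrices can also be read from and written to NEXUS (``DATATYPE=STANDARD``,
``SYMBOLS="01"``) and a simple TSV dialect.  Parsing is strict: states other
than 0/1 — including ``?`` — are rejected, because the analysis pipeline
has no missing-data semantics.
"""

from __future__ import annotations

import hashlib
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Optional, Sequence

import dendropy
import numpy as np

RClass = Literal["association", "disruption"]

_BUNDLED_NAME = "raptor_characters.tsv"
_BUNDLED_SHA256 = "a3c35da7f28b7aed7bc31d373e2c66218679de6bc6c2bb8c5ddef44e7f5541d1"


class MatrixParseError(ValueError):
    """Raised on malformed matrix input; carries a line number when known."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


@dataclass(frozen=True)
class CharacterDef:
    """One rearrangement character.

    ``index`` is 1-based (matching the published numbering), ``label`` names
    the GGA segments involved, and ``rclass`` records whether the derived
    state is a syntenic association or a syntenic disruption.
    """

    index: int
    label: str
    rclass: RClass
    notes: str = ""

    def __post_init__(self):
        if self.rclass not in ("association", "disruption"):
            raise ValueError(f"rclass must be association|disruption, got {self.rclass!r}")


_POSITIONAL = re.compile(r"(p|q|prx|med|dis|ter|[pq](prx|med|dis)?|-[0-9ab]+)+$")


def infer_rclass(label: str) -> RClass:
    """Heuristic classification of a character label.

    A label whose two sides are positional subdivisions of the *same*
    chromosome (``1p/1q``, ``3qprx/3qmed``, ``mic21-a/mic21-b``) denotes a
    fission and is a disruption.  Everything else — sides from different
    chromosomes, any side naming a microchromosome other than the first
    side's, a compound side with ``+``, or an unplaced ``seg`` segment —
    denotes a fusion and is an association.

    The bundled fixture stores ``rclass`` explicitly; this function exists so
    the stored assignment can be audited and so externally supplied matrices
    get a sensible default.
    """

    if "+" in label or "seg" in label:
        return "association"
    sides = label.split("/")
    if len(sides) != 2:
        return "association"

    def core(side: str) -> str:
        side = side.strip()
        m = re.match(r"(mic\d+|mic-\w+|\d+)", side)
        return m.group(1) if m else side

    a, b = (core(s) for s in sides)
    return "disruption" if a == b else "association"


@dataclass
class CharacterMatrix:
    """Taxa x binary characters, with per-character metadata.

    ``states`` is a uint8 array of shape (n_taxa, n_characters) holding only
    0/1.  Taxon order and character order are meaningful and preserved by
    all I/O round-trips.
    """

    taxa: list[str]
    characters: list[CharacterDef]
    states: np.ndarray
    outgroup: str
    otu_members: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.uint8)
        problems = validate_matrix(self).violations
        if problems:
            raise ValueError("invalid matrix: " + "; ".join(problems))

    # -- basic accessors -------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def taxon_index(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"unknown taxon {taxon!r}") from None

    def column(self, char_index: int) -> np.ndarray:
        """States of the 1-based character ``char_index`` across taxa."""
        if not 1 <= char_index <= self.n_characters:
            raise KeyError(f"character index {char_index} out of range")
        return self.states[:, char_index - 1]

    def character_states(self, char_index: int) -> dict[str, int]:
        col = self.column(char_index)
        return {t: int(col[i]) for i, t in enumerate(self.taxa)}

    def derived_taxa(self, char_index: int) -> frozenset[str]:
        """Taxa carrying state 1 for a character."""
        col = self.column(char_index)
        return frozenset(t for i, t in enumerate(self.taxa) if col[i])

    def rclass_counts(self) -> dict[str, int]:
        out = {"association": 0, "disruption": 0}
        for c in self.characters:
            out[c.rclass] += 1
        return out

    def drop_taxa(self, taxa: Sequence[str]) -> "CharacterMatrix":
        keep = [i for i, t in enumerate(self.taxa) if t not in set(taxa)]
        return CharacterMatrix(
            taxa=[self.taxa[i] for i in keep],
            characters=list(self.characters),
            states=self.states[keep, :],
            outgroup=self.outgroup,
            otu_members=dict(self.otu_members),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (self.taxa == other.taxa
                and [(c.index, c.label) for c in self.characters]
                == [(c.index, c.label) for c in other.characters]
                and np.array_equal(self.states, other.states)
                and self.outgroup == other.outgroup)


@dataclass(frozen=True)
class ValidationReport:
    """Violations make a matrix unusable; warnings are informational."""

    violations: list[str]
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_matrix(matrix: CharacterMatrix) -> ValidationReport:
    """Check structural invariants; flag parsimony-uninformative characters.

    Constant (all-0 or all-1) characters are legal but contribute no signal
    to tree choice, so they are reported as warnings.
    """

    violations: list[str] = []
    warnings: list[str] = []

    if len(set(matrix.taxa)) != len(matrix.taxa):
        dupes = sorted({t for t in matrix.taxa if matrix.taxa.count(t) > 1})
        violations.append(f"duplicate taxa: {dupes}")
    if matrix.outgroup not in matrix.taxa:
        violations.append(f"outgroup {matrix.outgroup!r} is not among the taxa")
    if matrix.states.shape != (len(matrix.taxa), len(matrix.characters)):
        violations.append(
            f"state grid shape {matrix.states.shape} does not match "
            f"{len(matrix.taxa)} taxa x {len(matrix.characters)} characters")
    else:
        bad = np.argwhere(matrix.states > 1)
        for i, j in bad:
            violations.append(
                f"non-binary state {int(matrix.states[i, j])} at "
                f"taxon {matrix.taxa[i]!r}, character {j + 1}")
        for j, char in enumerate(matrix.characters):
            col = matrix.states[:, j]
            if col.min() == col.max():
                warnings.append(
                    f"character {char.index} ({char.label}) is constant: "
                    "parsimony-uninformative")
            elif col.sum() == 1 or col.sum() == len(col) - 1:
                warnings.append(
                    f"character {char.index} ({char.label}) is an autapomorphy: "
                    "parsimony-uninformative")
    indices = [c.index for c in matrix.characters]
    if indices != list(range(1, len(indices) + 1)):
        violations.append("character indices must be contiguous from 1")
    return ValidationReport(violations, warnings)


# ---------------------------------------------------------------------------
# bundled fixture
# ---------------------------------------------------------------------------

def _bundled_text(name: str, sha256: str) -> str:
    data = resources.files("chromoclad.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != sha256:
        raise RuntimeError(
            f"bundled fixture {name} is corrupted: sha256 {digest} != expected {sha256}")
    return data.decode("utf-8")


def load_bundled_matrix() -> CharacterMatrix:
    """The published 59-character, 13-OTU matrix with GGA as outgroup.

    The fixture is checksummed; corruption raises rather than returning a
    silently altered matrix.
    """

    text = _bundled_text(_BUNDLED_NAME, _BUNDLED_SHA256)
    taxa: list[str] = []
    outgroup = ""
    members: dict[str, list[str]] = {}
    chars: list[CharacterDef] = []
    state_rows: list[str] = []
    for line in text.splitlines():
        if line.startswith("#taxa\t"):
            taxa = line.split("\t")[1:]
        elif line.startswith("#members\t"):
            for item in line.split("\t")[1:]:
                otu, rest = item.split("=")
                members[otu] = rest.split(",")
        elif line.startswith("#outgroup\t"):
            outgroup = line.split("\t")[1]
        elif line.startswith("#") or line.startswith("index\t") or not line.strip():
            continue
        else:
            idx, label, rclass, states, *rest = line.split("\t")
            notes = rest[0] if rest else ""
            chars.append(CharacterDef(int(idx), label, rclass, notes))  # type: ignore[arg-type]
            state_rows.append(states)
    grid = np.array([[int(s) for s in row] for row in state_rows], dtype=np.uint8).T
    return CharacterMatrix(taxa=taxa, characters=chars, states=grid,
                           outgroup=outgroup, otu_members=members)


# ---------------------------------------------------------------------------
# external formats
# ---------------------------------------------------------------------------

Dialect = Literal["nexus", "tsv"]


def parse_matrix(text: str, dialect: Dialect = "nexus",
                 outgroup: Optional[str] = None) -> CharacterMatrix:
    """Parse a matrix from NEXUS or TSV text.

    NEXUS input must carry a DATA/CHARACTERS block with standard 0/1
    symbols.  The TSV dialect is: a header line ``taxon\\t1\\t2\\t...`` of
    character indices, then one row per taxon.  Unknown state symbols
    (including ``?`` and polymorphisms) are an error — the pipeline is
    defined for complete binary data only.

    ``outgroup`` defaults to the first taxon.
    """

    if dialect == "nexus":
        taxa, rows = _parse_nexus(text)
    elif dialect == "tsv":
        taxa, rows = _parse_tsv(text)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    n_char = len(rows[0])
    chars = [CharacterDef(i + 1, f"c{i + 1}", infer_rclass(f"c{i + 1}"))
             for i in range(n_char)]
    grid = np.array(rows, dtype=np.uint8)
    return CharacterMatrix(taxa=taxa, characters=chars, states=grid,
                           outgroup=outgroup or taxa[0])


def _parse_tsv(text: str) -> tuple[list[str], list[list[int]]]:
    lines = [l for l in text.splitlines()
             if l.strip() and not l.lstrip().startswith("#")]
    if not lines:
        raise MatrixParseError("empty input")
    header = lines[0].split("\t")
    n_char = len(header) - 1
    if n_char < 1:
        raise MatrixParseError("header declares no characters", line=1)
    taxa, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        taxon, cells = fields[0], fields[1:]
        if taxon in taxa:
            raise MatrixParseError(f"duplicate taxon {taxon!r}", line=lineno)
        if len(cells) != n_char:
            raise MatrixParseError(
                f"taxon {taxon!r} has {len(cells)} states, expected {n_char}",
                line=lineno)
        row = []
        for j, cell in enumerate(cells):
            if cell not in ("0", "1"):
                raise MatrixParseError(
                    f"invalid state {cell!r} for taxon {taxon!r}, character {j + 1} "
                    "(only 0/1 supported; missing data is not)", line=lineno)
            row.append(int(cell))
        taxa.append(taxon)
        rows.append(row)
    if not rows:
        raise MatrixParseError("no taxon rows")
    return taxa, rows


def _parse_nexus(text: str) -> tuple[list[str], list[list[int]]]:
    try:
        dmat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:
        line = getattr(exc, "line_num", None)
        raise MatrixParseError(f"NEXUS parse failed: {exc}", line=line) from exc
    taxa, rows = [], []
    lengths = {}
    for taxon in dmat.taxon_namespace:
        seq = dmat[taxon]
        lengths[taxon.label] = len(seq)
    if len(set(lengths.values())) > 1:
        raise MatrixParseError(f"ragged rows: per-taxon lengths {lengths}")
    for taxon in dmat.taxon_namespace:
        row = []
        for j, cell in enumerate(dmat[taxon]):
            symbol = str(cell)
            if symbol not in ("0", "1"):
                raise MatrixParseError(
                    f"invalid state {symbol!r} for taxon {taxon.label!r}, "
                    f"character {j + 1} (only 0/1 supported; missing data is not)")
            row.append(int(symbol))
        if taxon.label in taxa:
            raise MatrixParseError(f"duplicate taxon {taxon.label!r}")
        taxa.append(taxon.label)
        rows.append(row)
    if not rows:
        raise MatrixParseError("NEXUS matrix contains no taxa")
    return taxa, rows


def write_matrix(matrix: CharacterMatrix, dialect: Dialect = "nexus") -> str:
    """Serialize a matrix so that :func:`parse_matrix` (and, for NEXUS,
    standard phylogenetic software) reads back an identical matrix."""

    if matrix.n_characters == 0:
        raise ValueError("refusing to serialize a matrix with no characters")
    if dialect == "tsv":
        out = ["taxon\t" + "\t".join(str(c.index) for c in matrix.characters)]
        for i, taxon in enumerate(matrix.taxa):
            out.append(taxon + "\t" + "\t".join(str(int(s)) for s in matrix.states[i]))
        return "\n".join(out) + "\n"
    if dialect != "nexus":
        raise ValueError(f"unknown dialect {dialect!r}")

    name_w = max(len(t) for t in matrix.taxa) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;',
        "    MATRIX",
    ]
    for i, taxon in enumerate(matrix.taxa):
        row = "".join(str(int(s)) for s in matrix.states[i])
        lines.append(f"        {taxon:<{name_w}}{row}")
    lines += ["    ;", "END;"]
    return "\n".join(lines) + "\n"
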