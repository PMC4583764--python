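"""Chromosome-painting homology maps (the "atlas").

Cross-species chromosome painting (ZOO-FISH) hybridizes whole-chromosome
probes from a reference species onto the metaphases of a target species;
each probe lights up the target chromosomes/segments homologous to that
reference chromosome.  The bundled atlas records, for the stone curlew
(BOE) and the diurnal birds of prey studied by painting, which target
chromosomes are homologous to chicken (GGA) chromosomes 1-5 — the
macrochromosomes whose syntenies are broken up in accipitrids.

Target labels are stored verbatim as published.  A label containing ``+``
(e.g. ``8p + q``) denotes a *single* fused chromosome and therefore counts
as one homologue; this convention is what makes the printed segment counts
("BOE 1 probe hybridized to seven pairs of GFU chromosomes") come out
right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .characters import _bundled_text

_BUNDLED_NAME = "painting_homologies.tsv"
_BUNDLED_SHA256 = "304c626c629107066d1666e2321a4cce5a8be00ec96efb5cf916d229620db872"


@dataclass(frozen=True)
class HomologyMap:
    """Homologues of the reference (GGA) chromosomes in one species.

    ``records`` maps a reference chromosome id (``"GGA1"`` ... ``"GGA5"``)
    to the ordered list of target chromosome/segment labels.
    """

    species: str
    two_n: int
    records: dict[str, tuple[str, ...]]
    source: str = "literature"
    pooled_with: tuple[str, ...] = ()

    def __post_init__(self):
        if self.two_n <= 0 or self.two_n % 2:
            raise ValueError(f"2n must be a positive even integer, got {self.two_n}")
        for ref, targets in self.records.items():
            if not targets:
                raise ValueError(f"{self.species}: empty target list for {ref}")
            if len(set(targets)) != len(targets):
                raise ValueError(f"{self.species}: duplicate targets for {ref}")

    @property
    def reference_chromosomes(self) -> tuple[str, ...]:
        return tuple(self.records)


class Atlas:
    """A collection of homology maps, indexable by species abbreviation.

    Some species have two published maps (GFU: an earlier literature map
    shared with GRU, and a present-study map shared with GHI).  Lookup by
    species returns the present-study map when both exist; ``source=`` can
    force a specific one.
    """

    def __init__(self, maps: list[HomologyMap]):
        self._maps = list(maps)

    def __iter__(self):
        return iter(self._maps)

    def __len__(self) -> int:
        return len(self._maps)

    @property
    def species(self) -> list[str]:
        return sorted({m.species for m in self._maps})

    def get(self, species: str, source: Optional[str] = None) -> HomologyMap:
        hits = [m for m in self._maps if m.species == species]
        if source is not None:
            hits = [m for m in hits if m.source == source]
        if not hits:
            raise KeyError(f"no homology map for {species!r}"
                           + (f" with source {source!r}" if source else ""))
        if len(hits) > 1:
            preferred = [m for m in hits if m.source == "present_study"]
            hits = preferred or hits
        return hits[0]


def load_bundled_atlas() -> Atlas:
    """Load the bundled homology tables (checksummed fixture).

    Species published jointly on one row (identical painting patterns)
    expand to one :class:`HomologyMap` each, e.g. the BME row also yields
    BNI and RMA maps.
    """

    text = _bundled_text(_BUNDLED_NAME, _BUNDLED_SHA256)
    maps: list[HomologyMap] = []
    header: list[str] = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        if not header:
            header = line.split("\t")
            continue
        fields = dict(zip(header, line.split("\t")))
        records = {ref: tuple(x.strip() for x in fields[ref].split(","))
                   for ref in header[4:]}
        pooled = tuple(x for x in fields["pooled_with"].split(",") if x)
        group = (fields["species"],) + pooled
        for sp in group:
            maps.append(HomologyMap(
                species=sp,
                two_n=int(fields["2n"]),
                records=records,
                source=fields["source"],
                pooled_with=tuple(s for s in group if s != sp),
            ))
    return Atlas(maps)


def count_homologues(homology_map: HomologyMap, ref_chrom: str) -> int:
    """Number of target chromosomes/segments homologous to ``ref_chrom``.

    Order-independent; a fused ``a + b`` label is one homologue.
    """

    if ref_chrom not in homology_map.records:
        raise KeyError(
            f"{homology_map.species}: unknown reference chromosome {ref_chrom!r} "
            f"(have {list(homology_map.records)})")
    return len(homology_map.records[ref_chrom])


def diff_maps(map_a: HomologyMap, map_b: HomologyMap) -> dict[str, tuple[tuple[str, ...], tuple[str, ...]]]:
    """Per-reference-chromosome symmetric difference of two maps.

    Returns ``{ref: (only_in_a, only_in_b)}`` for the reference chromosomes
    whose target sets differ; an empty dict means the maps are identical in
    content.  Both maps must cover the same reference chromosomes.
    """

    refs_a, refs_b = set(map_a.records), set(map_b.records)
    if refs_a != refs_b:
        raise ValueError(
            f"maps cover different reference chromosomes: "
            f"{sorted(refs_a ^ refs_b)} not shared")
    out = {}
    for ref in map_a.records:
        a, b = set(map_a.records[ref]), set(map_b.records[ref])
        if a != b:
            out[ref] = (tuple(sorted(a - b)), tuple(sorted(b - a)))
    return out
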