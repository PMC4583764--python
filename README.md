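# chromoclad

Chromosome-rearrangement cladistics for the diurnal birds of prey — and
for any small binary character matrix where an exact answer is wanted.

## The problem

Most birds share a strikingly conserved karyotype (2n ≈ 78–84, a few
macrochromosomes plus many microchromosomes).  Hawks, eagles and Old
World vultures (Accipitriformes) are the great exception: their genomes
have been reshuffled by dozens of fissions of the large chromosomes and
fusions involving microchromosomes.  Comparative chromosome painting
(ZOO-FISH) reveals these events as binary characters: either a species
carries a given derived *syntenic disruption* (a fission, e.g. `1p/1q` —
the two arms of chicken chromosome 1 are separate) or *syntenic
association* (a fusion, e.g. `5qprx/mic1` — proximal 5q joined to a
microchromosome), or it does not.  Treating each rearrangement as an
unordered, equally weighted presence/absence character turns karyotype
evolution into a cladistic inference problem: which tree of the painted
species requires the fewest chromosomal changes, which rearrangements are
clean synapomorphies marking clades, and which are convergences or
reversals?

`chromoclad` packages that entire analysis as tested, reusable code.  It
bundles the published 59-character × 13-OTU matrix for 17 diurnal birds
of prey (chicken, *Gallus gallus* GGA, as the outgroup) and the
chromosome-painting homology tables for chicken chromosomes 1–5, and
accepts external matrices as NEXUS or TSV.

## The method

For a binary character matrix over taxa and an unrooted topology `T`, the
tree length is the Fitch parsimony score

    L(T) = Σ_c  min #(state changes of character c on T)

computed by the Fitch set pass on binary trees (bit-packed, one machine
word per node) and by the unit-cost Sankoff dynamic program on
multifurcating trees.  The search for *all* most-parsimonious trees is
exact: depth-first branch-and-bound over stepwise leaf insertion, with
the partial-tree length plus a constant-character bound as an admissible
lower bound and strict-inequality pruning so that ties are never lost —
provably equivalent to exhaustive enumeration of all (2n−5)!! topologies.
Co-optimal binary trees that differ only in branches never required to
carry a change are condensed (the standard "collapse zero-length
branches" convention) before counting distinct MP trees.

The tree set is summarized by strict and 50% majority-rule consensus
(splits retained only above a *strict* majority).  Character changes are
then polarized a posteriori by the outgroup comparison criterion: each
tree is rooted on the outgroup's pendant edge, the root is fixed to the
outgroup's state, and every minimal reconstruction is enumerated as a set
of (branch, direction) events.  Characters are classified as unambiguous
(single stable reading), convergent-or-reversal (certainly homoplastic,
direction unstable) or ambiguous (uninterpretable against the topological
uncertainty); a synthetic-data module generates Yule trees and gain/loss
characters with known event logs so the whole chain is testable against
ground truth.  See `docs/methods.md` for conventions and design choices.

## Worked example

The full bundled analysis, from the command line:

```
$ chromoclad run
best length        : 68
MP trees (condensed): 10 (42 binary)
consensus          : (BBU,(((BNI,PAL),(((FCO,FPE),FTI),(GCA,GGA)),HHA),GBA),GFU,NNI,PHA);
unambiguous        : 53 (38 associations, 15 disruptions)
convergent/reversal: 3
ambiguous          : 3
```

Reading the output: the shortest trees for the 59 rearrangement
characters need 68 steps; there are 42 equally short binary topologies,
which collapse to 10 distinct trees once unsupported branches are
removed.  (The original study reports 67 steps with 10 trees; the
one-step difference traces to a parsimony-uninformative cell and is
analysed in `docs/methods.md`.)  The majority-rule consensus groups the
falconids, keeps the Neotropical buteonines (BNI+PAL) together, unites
the osprey (PHA) with the griffon vultures (GFU), the hawk-eagle (NNI)
and — notably — the Palearctic common buzzard (BBU), and leaves the
bearded vulture (GBA) and harpy eagle (HHA) at the unresolved base of the
accipitrids.  Of the 59 characters, 53 polarize unambiguously (38 fusions,
15 fissions), three (18, 33, 48) are convergences or reversals whose
direction cannot be fixed, and three (22, 41, 42) cannot be interpreted
against the unstable branching of GBA/HHA.

The same analysis as a library, plus a homology-map query:

```python
>>> import chromoclad as cc
>>> report = cc.run_full_analysis("bundled")
>>> report.best_length, report.n_mp_trees
(68, 10)
>>> matrix = cc.load_bundled_matrix()
>>> cc.clade_signature_characters(matrix, {"PHA", "GFU", "NNI", "BBU"})
[19, 30, 32]
>>> atlas = cc.load_bundled_atlas()
>>> cc.count_homologues(atlas.get("GFU"), "GGA1")
7
>>> cc.count_homologues(atlas.get("BBU"), "GGA1")
8
```

Three characters mark the osprey+vulture+hawk-eagle+buzzard assemblage,
and chicken chromosome 1 is split across seven griffon chromosomes but
eight buzzard chromosomes — the extra fission that distinguishes the
2n = 68 buzzard from the 2n = 66 vultures.

Simulated data with known truth:

```
$ chromoclad simulate --n-taxa 8 --n-chars 24 --conditioned --seed 33 -o sim.nex
$ chromoclad search sim.nex --all-trees mp.nwk
best length: 24
MP trees: 1 condensed (1 binary)
```

In the one-gain-per-character regime every character is a clean
synapomorphy and the unique MP tree is the generating topology.

## Layout

| Module                  | Contents                                                          |
|-------------------------|-------------------------------------------------------------------|
| `chromoclad.characters` | character matrix model, bundled fixture, NEXUS/TSV I/O, validation |
| `chromoclad.atlas`      | chromosome-painting homology maps and queries                      |
| `chromoclad.trees`      | tree container, Newick I/O, splits/clades                          |
| `chromoclad.parsimony`  | Fitch/Sankoff scoring, enumeration, branch-and-bound, condensation |
| `chromoclad.consensus`  | bipartitions, strict/majority consensus, Robinson–Foulds           |
| `chromoclad.polarize`   | outgroup rooting, minimal scenarios, character classification      |
| `chromoclad.simulate`   | Yule trees, gain/loss characters, recovery experiments             |
| `chromoclad.pipeline`   | `run_full_analysis` and the JSON run report                        |
| `chromoclad.cli`        | the `chromoclad` command                                           |
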