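# Methods

`chromoclad` implements a chromosome-based cladistic analysis for the
diurnal birds of prey: binary rearrangement characters scored from
comparative chromosome painting, an exact maximum-parsimony search,
consensus summaries, and a-posteriori polarization of every character
against the chicken outgroup.  This note records the models, conventions
and design choices behind each stage, and what the synthetic-data tests do
and do not demonstrate.

## Data model

### Characters

A character is the presence (1) or absence (0) of one derived chromosomal
rearrangement, named by the chicken (GGA) segments involved:

* **syntenic disruption** — a fission splitting a region contiguous in the
  reference karyotype (`1p/1q`, `3qprx/3qmed`, `mic21-a/mic21-b`);
* **syntenic association** — a fusion joining segments that are separate
  in the reference karyotype (`5qprx/mic1`, `1pdis/6`,
  `(5qdis + mic6)/(7 + mic8)`).

The bundled matrix has 59 characters over 13 operational taxonomic units
(OTUs), the chicken (GGA) being the only outgroup.  Species whose painting
patterns are identical are pooled into a single OTU labelled by the first
species (GCA = GCA+CAU; GFU = GFU+GHI+GRU; BNI = BNI+BME+RMA): their
matrix columns would be identical, and expanding them would only multiply
every topology by arbitrary permutations of zero-length branches.

Each character's class (association vs disruption) is stored explicitly in
the fixture and is reproduced by an auditable label heuristic
(`infer_rclass`): two positional subdivisions of the same chromosome are a
disruption; anything joining different chromosomes, a microchromosome, a
compound (`+`) side, or an unplaced `seg` segment is an association.  This
yields 18 disruptions and 41 associations.  Character 42 (`2qprx/2qdis`)
is kept as a disruption on structural grounds even though some published
per-species summaries group it with associations; the per-species tallies
printed for BBU (fourteen disruptions + ten associations) also exceed the
22 derived states of the BBU column.  Both inconsistencies are recorded in
the fixture notes; the matrix states themselves are transcribed verbatim.

Missing data is deliberately unsupported: the bundled matrix is complete,
and every pipeline stage assumes binary states, so `?` is a parse error
rather than a silently propagated unknown.

### Homology atlas

The atlas stores, per species, the chromosomes/segments homologous to GGA
1–5 (the macrochromosomes whose syntenies break up in accipitrids), with
the diploid number and data source.  Labels are verbatim; a label
containing `+` (e.g. `8p + q`) is a *single* fused chromosome and counts
as one homologue — the convention under which the printed segment counts
(seven GFU homologues of GGA 1, eight in BBU) come out right.  Two GFU
rows exist (an earlier map shared with GRU, and the present-study map
shared with GHI); lookups default to the present-study row.

## Parsimony scoring

Characters are unordered, equally weighted and binary, so tree length is
the Fitch length.  For fully resolved trees we run the classic Fitch set
pass with all characters packed two bits each into one machine integer per
node: a post-order traversal costs one bitwise merge per internal node
regardless of the character count.  Multifurcating trees (consensus trees,
user-supplied reference topologies) are scored with the unit-cost Sankoff
dynamic program, which minimizes exactly over ancestral states at nodes of
any degree; hard polytomies are scored as such, never by arbitrary binary
resolution.  For binary trees the two programs agree, and both are checked
in the test suite against brute-force enumeration of all ancestral-state
assignments.

## Exact search

With 13 OTUs there are (2·13−5)!! ≈ 1.37×10¹⁰ unrooted binary topologies —
naive enumeration is out of reach, but an exact search is not.  The search
is depth-first branch-and-bound over stepwise leaf insertion:

* inserting taxa in a fixed order (the matrix order), each new leaf on
  every edge, generates every topology exactly once — so the search is
  *provably equivalent to exhaustive enumeration*;
* the bound is the partial-tree Fitch length (adding leaves never
  decreases parsimony length) plus one step for every character still
  constant on the inserted taxa but variable overall;
* pruning is strict-inequality only, so ties are never lost and the
  returned set of optima is complete;
* the initial upper bound is the greedy stepwise-addition tree; no
  randomization is used anywhere, making the search deterministic, and the
  test suite verifies that the *set* of optima is invariant to taxon
  order.

On the bundled matrix the search scores ~3,000 partial trees and finishes
in well under a second.  The exact-search cap is 16 taxa; heuristic
searches for larger problems are out of scope.

### Condensation and the number of MP trees

Equally parsimonious binary trees often differ only in branches that no
minimal reconstruction ever places a change on.  Classic parsimony
software collapses such zero-maximum-length branches before counting
distinct trees, and `condense_trees` implements the same convention using
an inside/outside dynamic program (per branch: does *any* character change
there in *some* minimal reconstruction?).  On the bundled matrix the
complete set of binary optima has 42 topologies, which condense to 10
distinct trees; the pipeline reports both numbers.

### The bundled optimum: 68 steps, not 67

The printed matrix yields a best length of 68.  The original analysis
reports 67 steps with 10 trees.  Our transcription of the matrix is
validated against every per-clade character list and per-species tally the
source text prints, and the optimum of 68 was confirmed independently with
a second implementation (phangorn).  An exhaustive scan of all 767
single-cell edits finds none that yields 67 steps together with an
otherwise unchanged analysis; however, removing any one
parsimony-uninformative state (for instance one of the three identical
HHA-only characters 24–26) gives exactly 67 with an identical tree set.
The likely explanation is a one-cell difference between the matrix as
analysed and as printed.  The package computes and reports what the
printed data imply: L = 68, 10 condensed / 42 binary MP trees.

## Consensus

Bipartitions are canonicalized to the side not containing the smallest
leaf label.  The majority-rule consensus keeps splits occurring in
*strictly more than* the threshold fraction of trees (default 0.5), so a
split in exactly half the trees is excluded — the convention of standard
parsimony software; splits above a strict majority are pairwise
compatible, so the consensus always exists and is in general
multifurcating.  The strict consensus keeps splits present in every tree.
On the bundled data the majority-rule tree resolves the falconids, the
Neotropical buteonines (BNI+PAL) and the PHA+GFU+NNI+BBU assemblage, and
leaves a basal accipitrid polytomy; the instability concentrates on GBA
and HHA, which is where the 10 MP trees disagree.

## Polarization and classification

Each MP tree (and the consensus) is rooted on the outgroup's pendant
edge.  For every character, all ancestral-state assignments attaining the
parsimony minimum are enumerated by backtracking over the Sankoff tables,
with the root constrained to the outgroup's observed state (the outgroup
comparison criterion; because the root is adjacent to the outgroup leaf,
this constraint provably never costs an extra step).  Each assignment is
summarized as its set of *(branch, direction)* events — a minimal
scenario; branches are identified by the leaf set below them so scenarios
are comparable across trees.

The default classifier follows the original procedure: polarize along the
50% majority-rule tree, then grade each character by the stability of its
reading across the MP trees:

1. several minimal scenarios on the consensus → **ambiguous**;
2. a unique scenario with ≤ 1 change → **unambiguous** (a clean
   synapomorphy, autapomorphy, or stem loss);
3. a unique multi-event scenario (the character is homoplastic on the
   consensus): count the fraction of MP trees on which the character would
   instead be a clean single-change synapomorphy —
   * 0: **unambiguous** — the homoplasy is certain on every optimal tree
     and the consensus reading (e.g. a basal gain with one terminal
     reversal) holds everywhere;
   * ≤ `instability_tolerance` (default 0.2): **homoplastic** — the
     character is almost certainly a convergence or a reversal, but a
     minority resolution of the unstable taxa overturns which;
   * more: **ambiguous** — whether the character is homoplastic at all
     depends on the unresolved branching.

The tolerance operationalizes a judgment call that the original analysis
made by hand (its boundary between "convergent or reversal" and "hardly
interpretable" characters); 0.2 means "at most one dissenting tree in
ten".  On the bundled data this reproduces the published partition
exactly: 53 unambiguous characters (38 associations + 15 disruptions),
three convergent-or-reversal characters (18, 33, 48) and three
uninterpretable ones (22, 41, 42).  A stricter per-tree rule
(`mode="mptrees"`: unambiguous only with an identical unique single-change
scenario on every MP tree; homoplastic only with ≥ 2 changes on every
tree) is provided for comparison; on the bundled data it yields 47/4/8,
because characters 18, 33 and 48 are each a clean synapomorphy on exactly
one of the ten MP trees and therefore cannot satisfy a per-tree
homoplasy definition.

`map_characters_on_topology` applies the same tracing to any user-supplied
(possibly multifurcating) reference topology, e.g. a consensus of
molecular phylogenies, reporting per-character minimal counts and change
edges.

## Synthetic data

The generator emulates the statistical structure of rearrangement
characters — rare, mostly irreversible binary gains on a phylogeny — so
that every stage can be tested against known ground truth:

* **Tree**: Yule (pure-birth, unit rate) ingroup stopped at `n_taxa`
  leaves with one extra exponential grace period so terminal branches are
  never zero; an outgroup leaf attaches at the root, and both
  root-incident edges get length `outgroup_branch` (default 1.0).
* **Characters**: independent two-state Markov chains from root state 0
  (the ancestral karyotype lacks every derived rearrangement), gaining at
  `gain_rate` and reverting at `loss_rate` per unit branch length
  (defaults 0.3 and 0.03: gains rare on the Yule time scale, losses an
  order of magnitude rarer, mirroring the near-irreversibility of
  fusions/fissions).  The true event list (branch, direction, in time
  order) is returned alongside the matrix.
* **Conditioned mode**: exactly one gain per character.  The first
  characters cover each internal ingroup branch once — making the
  generating topology identifiable whenever `n_chars` is at least the
  number of internal branches — and the remainder fall on branches drawn
  with probability proportional to length.  Purely length-weighted
  placement was considered and rejected: on Yule trees short internal
  branches are missed with appreciable probability, in which case *no*
  method can recover the full topology and the mode would not serve its
  purpose of providing an analytically clean regime (every character a
  synapomorphy; the unique MP tree is the generating tree).

Seeding is hierarchical (`numpy` `SeedSequence`): one master seed,
per-purpose and per-replicate children, so experiments are reproducible
piecewise and bit-identical under a fixed configuration.

What passing the synthetic tests shows: the search, consensus and
polarization machinery is exact and consistent on data whose generating
process is known.  What it does not show: anything about the adequacy of
binary presence/absence coding for real karyotype evolution — the
generator has no chromosome-level mechanics (no breakpoint reuse, no
constraint that a segment lost to one fusion is unavailable to another,
no correlation between characters sharing a segment), all of which real
rearrangement data exhibit.

## Degenerate inputs and numerical conventions

* Constant and autapomorphic characters are legal and flagged as
  parsimony-uninformative warnings; they shift tree length but never tree
  choice (asserted by a test).
* Matrices with fewer than 3 taxa, trees above the enumeration cap (10
  taxa) or the exact-search cap (16), unknown outgroups, and leaf/taxon
  mismatches all raise with the offending names listed.
* Tie-breaking in stepwise addition is "first minimal insertion point" in
  a fixed traversal order; the greedy tree is only an upper bound, so this
  affects nothing downstream.
* `recovery_experiment` with zero replicates returns an empty summary
  rather than raising, so rate grids can include degenerate corners.

## Known limitations

* No missing or polymorphic states; no ordered or weighted characters; no
  Dollo/Camin–Sokal variants.
* No heuristic search: beyond 16 taxa the package refuses rather than
  silently approximating.
* The classifier's `instability_tolerance` is a modelling knob, not an
  estimated quantity; with ten MP trees its default separates "one
  dissenting tree" from "three", and users with different tree sets
  should choose it consciously (or use `mode="mptrees"`).
* Bootstrap/jackknife support is out of scope (single characters are
  events, not samples from a sequence alignment).
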