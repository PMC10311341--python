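# Methods

This note documents the models, parameters and numerical choices behind
`motifcompare`, and what the synthetic test corpus does and does not show.

## Problem setting

A motif instance is an ordered list of strand segments of nucleotides
(internal loops have two segments; the data model permits one to many, so
hairpin and multiloop motifs fit as well).  Two views of a motif drive the
analysis: its **base-interaction graph** — Leontis–Westhof base pairs
(interacting edge of each base: Watson–Crick/Hoogsteen/Sugar, plus cis/trans
orientation) and base stackings — and its **3D coordinates**.  Family-level
similarity is decided separately in each view, because the two views
genuinely dissociate: families can share isosteric interactions while folding
differently, and vice versa.

## Annotation merging

Two annotation sources per structure (DSSR-style and FR3D-style listings)
are merged: agreeing interactions are unioned, and conflicts — different
classes reported at the same residue pair, or one nucleotide edge claimed by
two partners — are resolved in favour of the interaction class that occurs
most often among the chain's *source-agreeing* interactions.  The counting
unit is the interaction class (edge × edge × orientation), not the
individual pair: class-level counting is the only reading that generalizes
to pairs not seen elsewhere on the chain.  Counts are taken over the loaded
corpus (optionally replaced by user-supplied precomputed counts, removing
any dependency on an external non-redundant structure list).  Ties prefer
interactions asserted by both sources, then the lexicographically smaller
class label — arbitrary but deterministic.  When *every* interaction of a
chain conflicts there is no context and the tie-break decides; such chains
are rare (disagreement-rate² per site) and accepted as noise.

## Interaction alignment

Matching two motifs' interaction graphs is formulated as maximum-weight
clique search on a match-compatibility graph: vertices are candidate
nucleotide matches (u, v); two candidates are compatible when they use
distinct nucleotides on both sides and preserve order within corresponding
segments; vertex weights carry a sequence-identity bonus and edge weights
the interaction-match scores.  Segment-to-segment correspondence is chosen
to maximize the score over all injective assignments.

Scoring defaults (config-exposed; all downstream statistics are
parameter-relative, never tied to absolute score values): full class match
3.0 (allowing the symmetric endpoint flip, e.g. tHS against tSH), partial
match 1.0, stack–stack 0.5 regardless of kind, identical-base bonus 0.3,
mismatch 0.0.  A **partial** match requires the same orientation *and* at
least one matching edge.  An orientation-only partial (both edges different)
is deliberately scored 0: with only two orientations, orientation-only
credit would make any two pair-bearing motifs score against each other and
manufacture interaction-mode similarity out of pure geometry.

The search is exact at motif scale.  It exploits the score structure:
only candidates whose nucleotides both carry interactions can realize edge
weights, so branch-and-bound enumerates those (bound: remaining potential
aggregated per nucleotide row/column, each realizable interaction charged
half to each endpoint), and once all are decided, the optimal completion by
sequence-bonus-only matches is a non-crossing maximum-weight matching per
segment pair, solved by an LCS-style dynamic program.  A node budget
(200 000) caps adversarial inputs; a greedy fallback exists for very large
candidate sets and is labeled heuristic.

Among equal-score optima the aligner is parsimonious: matches contributing
nothing to the score are pruned.  The alternative — padding alignments with
score-neutral matches — would extend every local alignment to
min(|A|, |B|) nucleotides, collapsing the local-versus-global distinction
between the two modes and contaminating the aligned-set RMSD with
geometrically unrelated residues.  Self-alignments still span the whole
motif, since every position carries the identity bonus.  Remaining ties
resolve by fixed search order (deterministic).

**Aligned length** is defined as the number of matched nucleotide pairs
(each contributing one aligned position per motif), used consistently on
both sides of every threshold comparison.

## Coordinate alignment

A global, order-preserving alignment optimizing a TM-score-type objective
over one representative backbone atom per nucleotide (C3′; fallbacks P,
then C1′ — configurable).  The distance scale follows the RNA convention
d₀ = 0.6·√(L − 0.5) − 2.5, floored at 3.0 Å because the formula goes
non-positive below L ≈ 70 and motifs here are an order of magnitude
shorter; L_target is the shorter motif's length, which keeps inter-family
comparisons symmetric.  Seeds are all gapless threadings (≥ 3 overlapping
positions) plus 4-nt fragment seeds on a stride-2 grid; each seed alternates
least-squares superposition on the current match set with a global DP pass
over the TM affinity matrix (gap penalty −0.6 per skipped interior position,
end gaps free; ties prefer the diagonal) until the match set repeats, up to
30 iterations.  Match sets already iterated by an earlier seed are not
re-explored (the continuation is deterministic), which removes most of the
redundant seed work.  The best TM-score over all visited states is returned.
The superposition is fitted to the full current match set rather than
searched over subsets; this is a documented simplification of the original
TM-score rotation search and is exact for the noise regimes tested.
No randomness anywhere; rigid-motion invariance holds to 1e-6.

## RMSD over aligned nucleotides

For each matched nucleotide pair the centroid of its backbone + ribose
heavy atoms is computed; the two centroid sets are superposed by Kabsch
(SVD with reflection correction) and RMSD taken over centroid pairs.
Per-nucleotide centroids were chosen over a single whole-motif centroid
because the latter would reduce every comparison to one point and make the
averaging in the formula vacuous.  RMSD is always computed after
superposition, in both modes — otherwise the value would depend on the
arbitrary crystal frame.  Nucleotides missing every scope atom are skipped
with a warning; superposition of fewer than three centroids falls back to
the same SVD machinery, which remains optimal for degenerate ranks.

## Family statistics and the similarity graph

* **Outlier filter**: per family and mode, each instance is summarized by
  its mean alignment score (interaction) or mean TM-score (coordinate)
  against same-family partners; instances with z < −2.0 (sample SD) are
  removed.  Families under three instances are not filtered; zero variance
  disables removal with a warning.
* **Length threshold**: the unrounded mean aligned length over intra-family
  pairs, post filter.  Singleton families have no threshold and never
  qualify.
* **Best pairs**: aligned_length ≥ max(threshold_A, threshold_B) and
  rmsd ≤ cutoff.  Cutoffs default to 1.0 Å (interaction) and 1.5 Å
  (coordinate); the looser coordinate cutoff compensates for the global
  aligner's obligation to place poorly fitting positions.
* **Participation**: share of a family's (post-filter) instances appearing
  in ≥ 1 best pair; the edge label takes the minimum over the two families;
  solid at ≥ 20%, dotted below.  Edge averages are unweighted means over
  the selected pairs.

Raising the RMSD cutoff can only grow, and raising the participation
threshold only shrink, the solid-edge set; the suite asserts this
monotonicity.

## Classifier utility analysis

Each motif is described by per-representative feature blocks (interaction
mode: score, aligned length, RMSD, matched pairs, matched stacks;
coordinate mode: aligned length, RMSD, TM-score; block order fixed by
family name).  The representative of a family is the instance with the
highest mean intra-family score, ties to lowest mean RMSD, then smallest
id.  Binary one-vs-rest Gaussian naive Bayes classifiers (variance
smoothing 1e-9) are evaluated with random undersampling of the negative
class to the positive-class size (drawn once per report; a flag redraws per
repeat) under stratified 3-fold cross-validation repeated 5 times; reported
metrics are mean accuracy, sensitivity (class-1 recall) and specificity
(class-0 recall) over the 15 runs.  The multiclass variant uses the same
protocol without undersampling.  Features are standardized for the PCA
projection utility only — naive Bayes is per-feature scale-equivariant
through its variances, so standardizing before GNB would be a no-op.

## Synthetic corpus

The generator emulates the pipeline's three inputs with controlled ground
truth.  Families are two-strand internal loops (7 + 7 nt) on
family-specific helical backbones (radius 6.5–13 Å, rise 2.5–3.6 Å, twist
30–100°, a strand-2 kink, and a per-family origin offset keeping family
frames ≥ 18 Å apart).  Each strand's first two positions form the family
core: two signature base pairs with a conserved purine sequence; the
remaining five positions per strand form a slot carrying a random sequence
and no interactions.  Atom sets are backbone + ribose heavy atoms only (the
RMSD scope); base rings are omitted, so fixtures are not physical RNA and
are labeled synthetic.  Per-atom isotropic Gaussian noise (default
0.12 Å, quantized to PDB precision) differentiates instances.

Planted relations inject shared structure into a chosen fraction of two
families' instances: *interaction* planting fills the slots with a dedicated
five-pair class set, a conserved pyrimidine sequence and the slot block's
own local geometry (shared interactions and local shape inside divergent
global shapes); *coordinate* planting replaces the whole instance's
coordinates with a shared template while keeping family-typical
interactions; *both* planting replaces coordinates, sequence and pair
classes wholesale.  Core sequences of planted family pairs are chosen with
no common in-order subsequence, so chance sequence matches cannot
contaminate the planted alignments' RMSD.  Annotation-source disagreements
are injected as cis/trans flips at a configurable rate (default 0.1) in the
FR3D-style file only, exercising the merge rule.

Stackings are generated only when a family spec asks for them and are off in
the default planted corpus: with a uniform positive stack score and stacks
on every consecutive pair, stack–stack matches would make every interaction
alignment effectively global and erase the planted local signal.  They are
exercised in unit tests instead.

What passing on this corpus shows: the pipeline's statistics recover planted
interaction-only, coordinate-only and both-mode similarity at the planted
participation levels, and reject unplanted pairs, under realistic annotation
noise.  What it does not show: performance on real RNA geometry (sequence
realism, base-ring atoms, modified bases at scale, experimentally determined
interaction networks), nor agreement with any external aligner's absolute
scores.

## Problem sizes

Default study conditions: six families × 10 instances, all-pairs alignment
in both modes (1 770 pairs each), classifier analysis on three families
(30 motifs × 3 representatives).  The full pipeline runs in about a minute
on one core; the acceptance script and the test suite each stay well inside
a few minutes.

## Known limitations

* The interaction-alignment scoring scheme is a transparent stand-in, not a
  reproduction of any published isostericity matrix; conclusions should be
  drawn from parameter-relative quantities (thresholds, participation), as
  the pipeline does.
* The coordinate aligner is motif-scale; it is not intended for whole
  chains, and its simplified superposition search can underestimate the
  TM-score of adversarial decoys.
* Base triples are not modeled; a nucleotide edge participates in at most
  one merged pair.
* The z-score filter assumes roughly unimodal intra-family summaries;
  strongly bimodal families (as arise at 50% planting) are kept whole,
  which is the desired behavior here but worth knowing about.
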