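# Methods

## Diagnostic-character model

The scanner treats a multiple sequence alignment column as a candidate
synapomorphy of a focal clade under four clauses, applied literally per
column with no tree in hand:

1. all focal taxa with data share one state *d* (focal invariance; missing
   symbols `N`, `-`, `?` and IUPAC ambiguity codes do not break invariance
   but increment the column's `missing_count`);
2. the modal state *a* among outgroup taxa with data reaches
   `outgroup_majority_threshold` (default 0.9, range (0.5, 1]) — the
   "mostly invariant" outgroup;
3. *a* ≠ *d*;
4. in strict mode (`forbid_derived_in_outgroup`, default on) no outgroup
   taxon carries *d*.

If clause 2 fails but *d* is absent from every observed outgroup state, the
column is still reported with an *unknown ancestor* (`state_only`), which
reproduces the bare `169A` notation class without inventing a polarisation.
Columns with no data on either side are *uninformative*, which the audit
table distinguishes from rejection.  This is a selection procedure, not a
probabilistic model: no likelihood is attached to a character.

Ranking is `(missing_count ascending, min_coverage descending, locus order,
position)` truncated to `top_k` (default 6, the typical printed diagnosis
length).  `min_coverage` is the *weakest-link* depth: the minimum read
depth over focal taxa that actually have data at the position.  Masked
cells carry depth 0, and including them would collapse the coverage
tie-break into the missing-count rank that already sorts first.
`max_focal_missing` defaults to |focal| − 1, i.e. at least one focal
observation.

Outgroup taxa with missing data are not grounds for exclusion; their count
is recorded in the audit table so a user can apply a stricter policy
downstream.

### Singleton clades

A clade with one sequenced species cannot be diagnosed directly (every
private state would qualify), so `scan_singleton` unions two character
sets: (a) *retained* characters at sister-clade synapomorphies — the focal
taxon must carry the ancestral state; if it is missing there, or carries
the sister's derived state, or a third state, the position is dropped,
since "retains the ancestral state" is then not demonstrable — and (b)
derived synapomorphies of focal+sister against the parent clade's
outgroup.  Duplicates are merged by position identity and re-ranked.

## Notation codec

Four dialects: `aly728.44.1:G672C` (derived), `aly5294.20.2:A548A (not C)`
(retained, single space before the parenthesis on render, flexible
whitespace on parse), `169A` (unknown ancestor), and bare barcode
coordinates `A79T` / `59C` limited to positions 1–658.  The
scaffold.gene.exon prefix accepts any lowercase reference tag, not just
`aly`.  Parsing is the exact inverse of rendering; errors carry the string
offset of the failure.  Positions are 1-based and closed within each exon,
matching how the notation addresses the reference exon frame.

## Barcode distances and association

Uncorrected p-distance only (the published comparisons are raw bp counts
and percentages; no Jukes–Cantor or K2P correction): mismatches are counted
at sites where both sequences have a definite base, and `n_compared` is
always reported next to the percentage because historical specimens can
have substantial missing data.  Percent display rounds half-up to one
decimal; full precision is kept internally.  Specimen association is
single-linkage grouping at `p < threshold` (strict inequality, implemented
as connected components of the thresholded graph), with a 2% default that
sits in the wide gap between the ~0.15% within-species and ~8.8%
between-species differences the motivating comparison shows; any threshold
in that gap gives the same partition.

## Trees and the rank rule

Neighbor joining (via scikit-bio) on p-distance matrices of a concatenated
partition stands in for heavyweight ML inference; the package's
contribution is the support bookkeeping and the rank logic above it, so the
tree builder is deliberately the simplest method that is exact on additive
matrices (negative NJ branch estimates are clamped to zero).  Bootstrap
support of a clade is the percentage of column-resampled replicates whose
NJ tree, rooted on the same outgroup, contains the clade; a singleton taxon
is trivially a clade at 100%.  Supports are written as internal-node labels
in newick.

`rank_decision` grants the subfamily recommendation iff in **every**
partition tree (i) the *inclusion* clade (focal plus all candidate sister
lineages) is supported at ≥ `strong_threshold` (default 95, between the
published "weak" 65–89% and "strong" 97–100% values) and contains the
focal lineage, and (ii) the *exclusion* reference clade is supported at
≥ threshold and excludes it.  The bootstrap value at the focal lineage's
attachment node is recorded but never consulted: the rule is exactly the
argument that rank does not require a resolved placement, only a resolved
membership and a resolved non-membership, and it therefore returns the same
recommendation under all three possible placements of the focal lineage
within the inclusion clade.  Relative divergence timing, which the verbal
argument also leans on, is not modelled — only topology and supports.

## Synthetic-data generator

The generator emulates the downstream shape of a multi-genome exon
dataset, not the sequencing itself: no reads, no indels, no alignment
error, no among-site rate variation.

* **Tree**: pure-birth (Yule) with rate 1.0 per lineage, or a fixed newick.
  The focal clade is made monophyletic by construction (a placeholder tip
  on the backbone is replaced by an independently grown subtree), so
  ground truth exists.  `tree_scale` (default 0.05 expected substitutions
  per site per unit depth) keeps tip-to-tip divergence in the few-percent
  range typical of congeneric-to-confamilial exon data.
* **Sequences**: JC69 (default) or GTR; per-branch transition matrices are
  `expm(Q·t)` with Q normalised to one expected substitution per site per
  unit length, so JC69 pairwise differences follow
  `p = 3/4·(1 − e^(−4d/3))`, which the tests check at saturation and
  mid-range.
* **Planting**: `n_planted` positions (default 10) are overwritten — clade
  taxa set to *d*, all others to *a* — rather than constraining the
  simulator, trading realism for exact ground truth.  Planted positions can
  coincide with natural variation; the background also produces genuine
  synapomorphies on the focal stem branch, so exact-recovery checks
  (recall 1.0, zero false positives) run the evolver at a zero substitution
  rate, where planting is the only signal.  With background evolution on,
  the guaranteed property is that the planted set is a subset of a strict
  scan's output.
* **Missingness/coverage**: i.i.d. per-cell Bernoulli masking (default 5%)
  to `N`, and per-cell negative-binomial read depth (mean 25, dispersion 5
  — moderate-coverage shotgun data with realistic overdispersion; no
  published coverage model exists to copy).  Unmasked cells are floored at
  depth 1; masked cells get 0.
* **Layout**: `n_loci` (default 20) exon loci of `locus_length` (default
  300 bp) cycled over nuclear/nuclear/nuclear/Z/mito partitions, plus one
  658-bp COI barcode locus, so the barcode partition always concatenates to
  the standard frame.  Taxon names follow the NVG-voucher pattern of
  museum DNA samples.

Determinism: one global seed; evolution, planting and masking derive
per-locus streams at distinct fixed offsets, so identical configs give
bit-identical alignments, coverage, trees and downstream outputs (the
pipeline test compares reruns byte-for-byte).

Because the generator omits alignment error, paralogy, contamination,
heterozygosity and rate variation, passing tests demonstrate correctness of
the *procedures* on clean data with known truth — not robustness of the
characters to real-data artefacts.

## Problem sizes and runtime choices

Defaults (12 taxa × 21 loci, 100 bootstrap replicates) run the full
pipeline in a few seconds on one core.  The test-suite and acceptance
sizes — 200 random ≤8×50 alignments for the oracle comparison, 100 random
6-taxon trees for NJ recovery, 10,000–30,000 sites for closed-form
substitution checks, 30 bootstrap replicates in the determinism rerun —
were chosen as the smallest sizes at which the binomial 3σ bands and exact
checks are meaningful.

## Known limitations

* No tree-based ancestral-state reconstruction: polarisation is by
  outgroup comparison only, as in the procedure being reproduced.
* `state_only` emission depends on the majority threshold, so a character
  can change class (derived ↔ unknown-ancestor) as the threshold moves,
  though the reported position set only grows as the threshold drops.
* NJ on non-additive (noisy) matrices has no optimality guarantee; supports
  quantify resampling stability, not model adequacy.
* The rank rule encodes membership/exclusion support only; divergence-time
  arguments for rank are out of scope.
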