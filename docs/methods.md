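# Methods

This note documents the models, conventions, and numerical choices behind
`cwrphylo`, and what the synthetic-data experiments do and do not show.

## Trees and patristic distances

All distance work happens on rooted trees with uniquely labelled tips and
non-negative branch lengths. Input Newick is trusted as rooted; a basal
polytomy is accepted as a rooted polytomy (the original analyses root with
an outgroup, which we do not re-derive). Negative branch lengths — which
maximum-likelihood optimizers occasionally emit — are clamped to zero, and
missing lengths are treated as zero, both with logged warnings. Taxon names
are matched exactly after canonicalization (trim outer whitespace, collapse
internal whitespace/underscore runs to `_`); no fuzzy taxonomy is
attempted.

The patristic distance PD(i, j) is the sum of branch lengths along the
unique tip-to-tip path. Matrix construction is delegated to dendropy's
phylogenetic distance machinery; the test suite checks it entrywise
(tolerance 1e-10) against an independent brute-force oracle that walks both
tips' ancestor chains to the root.

### Ultrametric transformation

Published trees are additive, not ultrametric, and the screening threshold
is defined on a height-normalized ultrametric tree. Two topology-preserving
transforms are provided; the method used is recorded in output metadata
because thresholds depend on it.

- **Mean path length** (default, `mpl`): each node's height is the mean of
  its node-to-tip path lengths, tip-weighted so every descendant tip counts
  once. Heights are then clamped top-down so no child exceeds its parent,
  and branch lengths are rebuilt as height differences. Every root-to-tip
  path then equals the root height exactly (checked to 1e-8).
- **Least squares** (`ls`): node heights minimize the squared discrepancy
  between original branch lengths and parent–child height differences,
  tips fixed at height zero, followed by the same monotonic clamp.

Ultrametricity is verified as equal root-to-tip depths within a relative
tolerance of 1e-6 (equivalent to the three-point condition for rooted
trees). Zero-length branches are legal throughout; polytomies are accepted
and never resolved, since distance computations do not require binary
trees.

### Height normalization

An ultrametric tree of height H is rescaled by 1/H so the root-to-tip
height is exactly 1.0 (tolerance 1e-10; idempotent). Heights at or below
1e-12 (e.g. an all-zero star tree) are rejected as degenerate. On the
result every pairwise distance lies in [0, 2]. The scale factor and
original height are stored in tree metadata.

### Shared-taxon pruning

Comparing two markers requires restricting both trees to their common tip
set. Pruning suppresses unifurcations by summing their branch lengths, so
patristic distances among retained tips are preserved (checked to 1e-10:
matrix-of-pruned equals submatrix-of-full).

## Threshold inference and candidate prediction

The screen assumes cross-compatibility decays with phylogenetic distance,
so the outermost *documented* successful cross bounds the region worth
testing. For crop *c*, relatives whose evidence qualifies under the anchor
policy define

τ(c) = max over qualifying w of PD(c, w).

- **Anchor policy.** Default `y_and_ystar`: Y\* records ("successful with
  very low success") are still successful sexual crosses, so they may
  anchor. `y_only` is available where a stricter reading is wanted; τ under
  `y_only` never exceeds τ under `y_and_ystar`.
- **Boundary.** Candidates satisfy PD ≤ τ inclusively — the anchor itself
  must satisfy the rule.
- **Undefined thresholds.** With no qualifying relative in the matrix, τ is
  undefined and no predictions are emitted (a notice, not an error).
- **Fallback.** Several cultivated species have no crossing literature at
  all (taxon-group-classified or NI crops). For these the maximum distance
  to a congener in the matrix serves as an explicit surrogate radius,
  always labelled `confidence=fallback`. This reproduces the practice of
  listing congeneric candidates for unexplored crops without pretending an
  anchor exists.
- **Novelty.** A prediction is *new* unless the pair has any Y/Y\*/N record
  or the candidate already carries a gene-pool/taxon-group classification.
  N-evidence taxa inside the radius are emitted but flagged already-known:
  their incompatibility is documented, and they never count as new.
- **Determinism.** Predictions sort by ascending distance, ties broken
  lexicographically; distance ties between potential anchors resolve to the
  lexicographically smallest name. Reports round distances to 5 decimal
  places (the precision of the published table); full precision is kept
  internally.
- **Markers.** Per-marker predictions can be merged by union (any marker
  proposes; supporting markers annotated) or intersection (all markers
  agree). The published analysis reports markers side by side, which is the
  default (`none`).

Evidence conflicts resolve by precedence Y > Y\* > N > NI, independent of
record order. This is this package's rule; the source compendia aggregate
multiple references without stating one.

### Ploidy annotation

Cytotype sets (reported 2n counts) are compared as sets: shared cytotype if
they intersect, disjoint if both known and non-overlapping, unknown if
either is empty. Chromosome counts below 4 or odd are rejected as input
errors. The annotation is advisory — same-cytotype crosses are the
recommended first attempt — and never filters predictions.

### The packaged worked-example table

A digitized version of the published crop × relative distance table ships
as `data/table1.tsv` (316 entries, 19 crops, markers matK and ITS). Printed
cells often list several taxa against one value or range; the fixture
assigns the shared value/range to each taxon and marks the entry
`ambiguous_group`, preserving the printed information without inventing
per-taxon values. Genus-level "spp." rows are kept as placeholders and
excluded from per-taxon counting. In matrix-bypass mode the fixture's
crop rows are embedded in a star-additive matrix (d(i, j) = d(i, c) +
d(c, j)), which preserves every crop–relative distance; range cells use
their upper endpoint by default (`bound="high"`).

## Conservation gap accounting

Introduced-range records are removed first; all counts concern native
ranges. Per TDWG level-3 region the summary counts distinct native taxa,
single-region endemics (native range exactly one region; each endemic
therefore contributes to exactly one region, so regional endemic counts sum
to the global total), threatened taxa, taxa with zero ex situ accessions,
and underrepresented taxa (1–4 accessions; 5 or more counts as
represented). "Threatened" means the IUCN band CR ∪ EN ∪ VU — the
conventional reading; NT and DD are counted separately, and assessments
from non-IUCN sources must be pre-mapped to the category enum by the user.
Taxa without a conservation record are treated as not evaluated with zero
accessions, with a warning. Region codes are opaque strings; no geometry
is computed.

## Synthetic data

The generator emulates the structure of the real study inputs so that every
stage runs without downloads and estimator behaviour is measurable.

- **Tree.** Pure-birth (Yule) process, default 200 tips: with k lineages
  the next split waits Exp(k·λ) and hits a uniform lineage; after the last
  split one further waiting time extends all tips, so terminal branches are
  positive. The tree is then height-normalized, so the birth rate only
  shapes relative node depths. Pure birth (death rate zero) is sufficient
  to produce realistic distance spreads on a height-1 tree. The test suite
  cross-checks mean pairwise distance against an independent
  re-simulation of the same process that never builds tree objects.
- **Evidence.** Default 18 crops. Each crop draws a true compatibility
  radius r uniformly from [0, 0.2] (the range spanned by the published
  per-crop thresholds on height-1 trees). Taxa within r are compatible;
  those within `anchor_radius_scale · r` receive Y (a quarter of them Y\*),
  compatibles beyond the anchor window stay NI (untested), taxa beyond r
  receive N. Every generated record is independently blanked to NI with the
  missing rate (default 0.3, reflecting how sparse crossing literature is).
- **Ploidy.** 2n starts at 16 at the root (x = 8 is a common base number in
  the family); per branch, Poisson(rate × length) whole-genome duplications
  double it and dysploidy events step it by ±2, floored at 4. Tips
  occasionally (p = 0.1) retain the parental cytotype alongside their own,
  giving multi-cytotype taxa.
- **Conservation.** Region counts are zeta-distributed (dispersion 1.81,
  giving a single-region probability of ≈ 0.536 — about half the taxa
  endemic, as in the family-wide census of 667/1242), truncated at the
  region count; threat categories are sampled so ≈ 35% of taxa carry an
  assessment and ≈ 27% of the assessed are threatened; accession counts are
  zero-inflated (p₀ = 0.63, matching 787/1242 taxa absent from ex situ
  collections) with a geometric tail (p = 0.15). A 10% introduced-record
  rate exercises the native filter.

One seeded numpy Generator is threaded through tree → evidence → ploidy →
conservation in that fixed order, so identical configs give byte-identical
bundles; standalone calls derive per-stage streams from the seed.

### What the recovery experiment shows — and does not

With noiseless evidence, τ̂ equals the largest anchored distance exactly and
never exceeds r, so predicted and true compatible sets coincide
(sensitivity = specificity = 1). With anchors confined to r/2, τ̂ ≤ r still
holds, specificity stays 1, and sensitivity drops honestly — the estimator
is conservative by construction: it can only under-reach, never
over-reach, the true radius. These guarantees are properties of the
estimator under the generator's assumptions (compatibility exactly
thresholded on patristic distance, evidence missing at random). Real
crossing data violate both — compatibility also depends on ploidy,
genome structure, and direction of the cross, and the literature is biased
toward major crops — so passing these tests validates the pipeline's
bookkeeping, not the biological sufficiency of distance thresholds.
Accordingly, no attempt is made to reproduce the published 103-taxon
candidate list, which depends on archived sequence snapshots and
supplementary-data resolution of genus-level groups.

## Problem sizes

Default test and acceptance runs use 200 seeded trees of 5–100 tips for the
oracle sweeps, 100 replicates of 50-tip/5-crop simulations for threshold
recovery, and 500–1242-taxon conservation tables — sizes at which every
behaviour under test is already exercised while the full suite stays fast.

## Known limitations

- Distances from a published table enter as printed (5–6 significant
  digits); grouped cells carry a shared range, so per-taxon exactness is
  limited to single-valued cells.
- The least-squares ultrametric transform clamps negative or non-monotone
  heights after an unconstrained solve rather than solving the constrained
  problem; for trees close to clock-like the two coincide.
- Evidence precedence (Y > Y\* > N > NI) discards conflict information; a
  pair with both Y and N records surfaces as Y.
- The fallback (maximum-congener) threshold is a stated convention for
  anchor-free crops, not an inference.
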