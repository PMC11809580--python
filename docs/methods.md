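# Methods

## The question

When a single taxon `s` is added to (or, equivalently, removed from) a
phylogenetic inference, does the topology of the tree on the remaining
taxa change — and if so, where, by how much, and was the change
predictable without re-running the inference?  `treestab` implements this
leave-one-out analysis end to end: stability measures, significance
testing, placement-based summary statistics, and learned predictors, all
exercised against synthetic data with known ground truth.

Notation: `T*` is the tree inferred on the full alignment `A`; `A−s` is
the alignment without taxon `s`; `Ts*` is the tree inferred on `A−s`
("inferred tree"); `Ts` is `T*` with leaf `s` pruned ("pruned tree");
`Ts+` is `Ts*` with `s` re-attached at its best placement edge.

## Stability measures

**Taxon influence index (TII).**  `TII(s) = d_RF(Ts, Ts*)`, the
Robinson–Foulds distance (size of the symmetric difference of the
nontrivial split sets).  `TII = 0` means the inference is stable for `s`.
The normalized TII divides by `2(m−3)`, the maximum RF distance between
binary trees on `m` leaves, where `m` is the leaf count of the two
compared trees (the `(n−1)`-taxon trees; with `m = 3` the normalization is
defined as 0 since only one topology exists).

**Disruption radius.**  How far from `s`'s attachment edge in `T*`
topology changes propagate.  A `T*` edge counts as *present* in `Ts*` if
its split, after deleting `s`, is trivial or induced by some `Ts*` edge.
The raw radius is the maximum node-count distance from `s`'s pendant edge
to any absent internal edge; it is normalized by the maximum distance from
the pendant edge to any internal edge.  Topological distance between two
edges counts the nodes on the connecting path inclusively: 0 for the same
edge, 1 for adjacent edges.  (Whether endpoint nodes are counted is a
convention; the inclusive choice is used consistently, and the
normalizations make most ratios insensitive to the constant shift.)

`TII(s) = 0` iff the disruption radius is 0: pruning a binary tree maps
its splits onto exactly the `m−3` splits of `Ts`, so "every reduced split
present" is equivalent to split-set equality.  The acceptance suite checks
this equivalence on every fixture row and checks the radius against an
exhaustive brute-force scan.

**Distance of unstable edges to low support.**  For each `Ts*` internal
edge absent from `Ts`, the node-count distance to the nearest edge with
bootstrap support below 70%, normalized per edge by that edge's maximum
distance to any internal edge, averaged over unstable edges.  Undefined
(reported as missing, never 0) in stable cases.  When `Ts*` has no
low-support edge at all the per-edge term is set to 1.0 ("far from any
uncertainty") with a log note — this case has no canonical definition.

## Significance of instability

For unstable taxa (`TII ≠ 0`) the pruned tree is tested against the
inferred tree.  Branch lengths of both topologies are re-optimized under
the model; per-site log-likelihoods are tabulated; then:

* **RELL resampling** draws multinomial site weights (resample size
  `round(scale × sites)`) and forms replicate total log-likelihoods
  without re-optimizing.
* **SH test**: replicate totals are centered per tree; the null
  distribution of "best minus tested" differences is compared with the
  observed difference; ties count in favour of the tested tree, so
  identical likelihood rows give p = 1.
* **AU test**: multiscale bootstrap over scales 0.5–1.4 (step 0.1, 1000
  replicates per scale).  Per scale, the bootstrap proportion of
  replicates in which the tested tree attains the maximum ("equally good
  or better": ties are awarded to the tested tree) is probit-transformed
  and fitted as `z(r) = d·√r + c/√r` by weighted least squares with
  binomial-variance weights; `p = 1 − Φ(d − c)`.  Proportions degenerate
  at every scale map to p = 0 or 1; fewer than two informative scales fall
  back to the SH p-value with a warning.

"Significant instability" means `TII ≠ 0` and AU p < 0.05.  SH p-values
are stored alongside so either test can drive the label.  Calibration is
verified on a simulated null (near-star quartet, both resolutions
equivalent): the SH rejection rate at α = 0.05 stays within [0.01, 0.10];
power is verified on strong-signal data against NNI-perturbed topologies.

## Likelihood machinery

Felsenstein pruning over reversible nucleotide models (JC69, K2P, HKY,
GTR) with optional discrete-gamma rate heterogeneity (4 equal-probability
categories, category rates by the mean method, mean 1).  The rate matrix
is scaled to one expected substitution per site at stationarity.  Gaps and
IUPAC ambiguity codes are partial-likelihood vectors (all-ones for fully
missing), so an all-gap column contributes likelihood 1.  The engine
caches, for every directed edge, the subtree message transported across
it; this makes total likelihood evaluable at any point (the pulley
principle is a test), single-branch likelihood curves cheap (spectral
decomposition of the rate matrix is reused across evaluations), and
placement a three-message product.  Alignment columns are compressed to
unique site patterns; per-pattern scaling guards against underflow; branch
lengths are floored at 1e-9 only inside the matrix exponential.

**Corrected distances** use pairwise deletion (sites where both characters
are unambiguous).  JC69 and K2P use their closed forms, JC69+Γ the
gamma-corrected closed form, and all other families a pairwise
maximum-likelihood distance obtained by golden-section search on
[1e-9, 10], vectorized over all pairs (and over all bootstrap replicates
at once).  Saturated or undefined corrections cap at 10 substitutions/site
with a logged warning — the cap keeps NJ well-defined on noisy pairs.

## Inference backends

The pipeline is backend-pluggable:

* **nj** — Saitou–Nei Neighbor Joining on corrected distances, negative
  intermediate branch lengths clamped to 0; exact on additive matrices
  (verified to 1e-9 on random trees).
* **ml** — hill-climbing search alternating round-robin branch-length
  optimization (bounded derivative-free per branch on [1e-8, 10] to 1e-6;
  a sweep stops when it gains < 1e-3 log units) with NNI sweeps that score
  candidate rearrangements from cached subtree messages and accept only
  strict improvements.  NNI-only rearrangement is deliberate: adequate at
  these scales, bounded runtime.
* **external** — reads externally inferred trees (`full.nw` plus one
  `<sanitized-taxon>.nw` per reduced inference) so results from
  full-strength ML tools can be analyzed without invoking them.

Bootstrap supports are standard nonparametric (Felsenstein) bootstrap:
site-resampled alignments re-inferred with the same backend, each internal
edge annotated with the percentage of replicates containing its split.
The default is 100 replicates — a desk-scale default, exposed in config.
Supports from this stand-in are not numerically comparable to
ultrafast-bootstrap values; they feed the same `< 70%` threshold logic.

## Placement

A query taxon is attached to every edge of `Ts*`; the pendant length and
the attachment position along the edge are optimized by coordinate
descent (two rounds, per-coordinate tolerance 1e-6, pendant bounded by 10)
with all other branch lengths fixed.  Likelihood weight ratios are
computed over **all** edges via log-sum-exp; candidates are sorted by
decreasing LWR (ties broken by canonical split order) and truncated once
the cumulative LWR exceeds 0.99.  A cheap screen (midpoint attachment at
three pendant lengths) limits the full two-parameter optimization to edges
within 50 log units of the screening best; the remaining edges keep their
screened values, which still enter the LWR denominator but are numerically
zero weights.  Placements serialize to jplace v3.

## Summary statistics

One feature row per taxon addition, computed only from `Ts*` (with
supports), the placement, `Ts+`, and the alignment — never from `T*`, so
the features remain genuine predictors.  The battery: normalized mean/SD
of pairwise node-count distances between high-quality insertion edges
(normalized by the edge-pair diameter; a single dominant location is 0 by
convention); best-edge LWR and the number of high-quality locations; the
insertion branch length and pendant length (normalized by the mean branch
length of `Ts+`); the attachment offset `min(distal, b−distal)/b`
(defined 0 for a zero-length branch, its limiting value); the normalized
distance from the insertion edge to the nearest low-support edge (1.0 when
none exists); mean/SD of internal-edge supports; sequence/patristic
distance ratios to `s` (mean/SD) and their per-taxon comparison against
the closest sequence (mean/SD); the insertion-to-sister-clade distance
ratio `a_s/a_C`; the insertion height (patristic distance from the
attachment point to the nearest other leaf over half the leaf-pair
diameter); and the normalized NJ TII.  All SDs are population SDs (well
defined at N = 1).  An optional per-alignment difficulty score is a
pass-through column supplied externally, never computed here.

Two conventions were genuinely open and are fixed as follows.  The
closest-sequence comparison is computed per remaining taxon `t`:
`ratio_t(s)/ratio_t(c)` with `c` the taxon nearest to `s` in sequence
distance, then averaged (the alternative scalar reading would make its SD
identically 0 and carry no signal).  The sister clades around the best
insertion edge of the *unrooted* `Ts*` are resolved with a canonical
reference leaf: `C` is the leaf set on the far side of the insertion edge
from the lexicographically smallest leaf; at the near endpoint the
smaller of the two remaining subtrees is `C′` (ties break on the smallest
contained label).

## Predicting instability

Random forests (scikit-learn) over the feature battery.  Tasks:
classification of `TII = 0` vs `≠ 0`, classification of significant
instability, and regression of normalized TII and disruption radius.
Because stable/unstable classes are imbalanced, the TII classifier trains
a *batched* ensemble: `floor(majority/minority)` batches, each containing
every minority-class row plus an equal number of majority rows drawn
without replacement across batches.  Predictions are majority votes (ties
to the unstable class — the conservative call for a consumer deciding
whether to re-optimize); probabilities are averaged across forests for
ROC curves.  The significant-instability classifier and the regressors
use a single forest (no imbalance to correct by construction).

Hyperparameters are tuned by a seeded random search over: trees in
[10, 1000]; depth in [10, 1000] (log domain); minimum split and leaf
fractions in [1e-5, 1] (log domain, converted to counts at fit time);
max-features in {all, log2}; split criterion in {gini, log-loss, entropy}
(classification) or {squared error, absolute error, Friedman MSE, Poisson}
(regression); 200 trials by default, scored on a 60/20/20
train/validation/test split (validation AUROC / R²; the test split is
only touched for final evaluation, and for the TII classifier its larger
class is subsampled to equal size).  A group-aware split option keeps all
rows of one alignment on the same side.  Permutation importances
(10 shuffles) are averaged across batch forests, floored at 0, and
normalized to sum to 1.

## Synthetic data

Topologies are sampled uniformly over labelled binary trees (sequential
addition with a uniform edge choice — the simplest defensible null, and
enumerable at small n for the uniformity test); branch lengths are i.i.d.
exponential with mean 0.1 substitutions/site.  Sequences evolve site-
independently under the configured model (default
GTR{1,2,1,1,2,1}+F{.3,.2,.2,.3}+Γ(α=1), a generic transition-biased
parameterization); each site keeps one gamma category across branches.

Four scenario kinds supply ground truth: **clean** (internal branches
floored at 0.05 — strong signal, leave-one-out almost always stable);
**low_support_region** (a contiguous pair of internal edges shrunk to
5e-4, with the focal taxon adjacent to the region); **mosaic_taxon** (the
focal sequence concatenates two segments evolved from the recorded
internal states of two distant donor attachment points, preserving the
marginal substitution process while breaking tree-likeness);
**long_pendant** (the focal pendant branch ×10).

The **fixture suite** is 40 alignments (8–16 taxa, 500–2000 sites, half
clean and half cycling through the three engineered kinds) pushed through
the full pipeline with the NJ backend, 100 bootstrap replicates and the
default significance settings, yielding roughly 470 labelled rows of
which roughly a tenth are unstable — enough imbalance to exercise the
batched ensemble.  What the suite does *not* emulate: empirical taxon
sampling, indels, alignment error, model misspecification beyond the
engineered regimes, and maximum-likelihood-scale tree search (labels come
from the NJ backend).  A consequence worth stating plainly: with NJ as
the inference backend, the NJ-TII feature is computed by the same
estimator that defines the label, so the TII classifier's near-perfect
discrimination on the suite mostly reflects that coupling rather than
generic learnability.  The planted-signal experiment — labels defined as
a threshold function of two named features over otherwise random
columns — is therefore the sharper check of the learning machinery, and
passing tests on the suite say nothing quantitative about empirical data.

## Problem sizes and numerical choices

The test and acceptance runs use: the 40-alignment fixture suite above;
50 placement-recovery trials at 16 taxa × 2000 sites; 200 SH-calibration
trials on 4-taxon near-star data (200 sites); 50 AU-power trials at
8 taxa × 1000 sites; 60-trial hyperparameter searches in the acceptance
runs (the library default stays at 200; the search plateaus far earlier
at these data sizes).  Branch-length optimization before significance
testing stops at a 1e-2 log-unit sweep tolerance — the tested likelihood
differences between topologies are orders of magnitude larger.
Determinism: every stochastic step derives its generator from an explicit
seed (seeds derived for sub-stages stay below 2^31); reruns are
byte-identical, and the pipeline caches whole runs keyed by a content
hash of alignment plus configuration.

## Known limitations

* The NJ-backend labels make the suite's TII classification partly
  self-referential (see above); an external-backend run with trees from a
  full ML tool is the intended path for empirical work.
* Bootstrap supports are plain Felsenstein bootstrap at B=100; features
  depending on supports differ numerically from ultrafast-bootstrap-based
  values by design.
* The ML backend searches NNI space only and is not meant for large trees.
* No indel simulation; gaps are handled in likelihoods but never generated.
* Significance testing is the two-tree case (pruned vs inferred); the
  k-tree interfaces exist but the pipeline never builds larger sets.
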