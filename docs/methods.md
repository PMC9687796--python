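# Methods

## Data model

A molecule is a *count fingerprint*: a fixed-length vector of
nonnegative integers (substructure-environment counts folded to a
fixed length, 1024 by default).  Raw hashed feature→count maps are
folded by modulo-L accumulation (`fold_counts`), which conserves the
total count; any collision-summing fold is consistent with count-
fingerprint semantics, and the upstream fingerprinting software's
exact dialect is not reproduced.  A *screening library* is a
fingerprint matrix with activity-class labels; inactive background
molecules carry the reserved label `INACTIVE` and are screened but
never used as queries.

A class's homogeneity is summarised by its mean pairwise continuous
Tanimoto similarity over all unordered member pairs, computed via the
Gram matrix.  Published benchmark profiles (class sizes and these
similarities) are bundled under `siamvs/data/profiles/` and can be
turned into generator configurations at any size scale.

## Synthetic library generator

Benchmark collections are emulated, not reproduced: the only
statistics the published profiles pin down are class size and mean
within-class similarity, so any generative model matching those two is
admissible.  Ours is template copying:

* background distribution: each position is nonzero with probability
  `density` (default 0.05, giving ~51 nonzero positions at L = 1024,
  typical of folded ECFC-style vectors), with count 1 + Poisson
  (`count_scale` − 1), `count_scale` default 2.0;
* each class draws one template from the background, and each member
  copies a fraction ρ of template positions, redrawing the rest from
  the background;
* ρ is calibrated per class by bisection against the measured mean
  pairwise similarity of a 20-member pilot sample drawn from a fixed
  stream (tolerance ±0.03).  Targets below the background similarity
  level or above the template-copy maximum raise `CalibrationError`;
* inactives are drawn wholly from the background, so they share no
  template with any class;
* all-zero draws (possible at very small L·density) are patched with a
  single count so every molecule is a valid fingerprint.

Everything is deterministic under the configuration seed via a spawned
`SeedSequence` tree, so changing one class's parameters does not
perturb another's draws.

What this emulates — and what it does not: realised class structure
matches the published size/similarity profile, and harder (more
heterogeneous) classes are harder for every scorer, so method
*contrasts* behave qualitatively like real screening data.  It does
not model chemistry: no correlated substructures, no activity cliffs,
no shared scaffolds between classes.  Passing tests therefore
demonstrate that the architectures learn and the protocol measures
what it should, not that the published benchmark recall values are
reproduced — those depend on licensed data and stochastic training at
scale.

Pair supervision labels a pair 1 iff both molecules share an activity
class (two inactives do not).  Batches are balanced by default
(`pos_fraction` 0.5), sampled once per training run, with no self-
pairs.

## Scorers

All neural scorers run on a small reverse-mode autodiff engine
(`siamvs/_autodiff.py`) written for exactly the ops the architectures
need; its gradients are checked against central finite differences in
the test suite.  Weight sharing between twins is structural — both
branch evaluations reference the same parameter tensors — so the twins
cannot diverge by construction.

* **SMLP**: branch = one dense ReLU layer (1024 units by default,
  matching the default fingerprint length); measures = absolute
  difference (vector), exponential Manhattan (scalar), optional
  continuous Jaccard (scalar); fusion = broadcast addition of the
  scalar sum onto the vector; head = dense ReLU stack
  (1024, 512, 256, 128, 64) and a single sigmoid unit.  The same head
  is used for the two- and three-measure variants.
* **SCNN1D**: branch = two 1-D convolutions (64 filters, kernel 3,
  ReLU), each followed by max-pool 2, then flatten and a dense sigmoid
  layer onto 512 features; the optional third measure is Russel; the
  fused vector feeds one sigmoid unit directly.  Convolutions use
  "same" zero padding so the two pool stages take L → L/2 → L/4; the
  input length must be divisible by 4.
* **Decision hybrids**: components are trained independently and the
  hybrid score is exactly `max(score_a, score_b)`.
* **Feature hybrids**: one end-to-end parameter set.  The dense trunk
  reduces its fused 1024-vector through dense ReLU layers (1024, 512);
  the convolutional trunk's fused vector is 512 already; the two are
  combined elementwise (sum or max) and a single sigmoid unit scores
  the pair.  Trained from scratch — the design is one model with one
  loss.

Numerical choices:

* In-graph Jaccard guards the 0/0 case (both ReLU feature vectors
  zero) with a +1e-12 in the denominator, scoring such a pair 0.  The
  standalone `jaccard_continuous`/`tanimoto_score` functions raise
  instead: a silent 0/0 would corrupt rankings.
* The exponential Manhattan over wide feature vectors underflows to
  0.0 for distant pairs; this is benign (the gradient is 0 there).
* The written formula for the exponential Manhattan measure omits the
  absolute value under the sum; it is implemented as
  exp(−Σ|f_A − f_B|), the Manhattan distance the name announces.
* Russel on real-valued features uses the raw product sum without
  binarisation.
* Initialisation is seeded uniform fan-in, U(±1/√fan_in); optimisation
  is RMSprop (lr 1e-3, decay 0.9, eps 1e-8) on binary cross-entropy
  with 1e-12 clipping inside the logs.  Defaults: 20 epochs, batch 32,
  all configurable.  Training is bitwise deterministic under the seed.
* Elementwise maximum routes the gradient to the first argument on
  exact ties; max-pooling routes to the first maximal element of each
  window.

Where the wiring of the third measure was genuinely open, it is
applied to the twin feature vectors — consistent with how the first
two measures are defined — and the choice is confined to
`_fused_measures` so a raw-fingerprint variant would be a one-line
change.

## Screening protocol

`rank_database` scores every non-query molecule and sorts descending;
ties are broken by ascending molecule id, so rankings are
reproducible.  The query is excluded from its own ranked list (self-
retrieval would inflate recall).  `recall_at` keeps
`ceil(pct/100 · N)` top positions and divides retrieved same-class
actives by the same-class actives present in the screened partition.

`run_cv` stratifies the library into k folds (round-robin within each
label stratum after a seeded shuffle; k defaults to 5), trains the
scorer on pairs sampled from the k−1 training folds, draws
`queries_per_class` (default 10) random actives per class from the
held-out fold, ranks each against the remaining held-out molecules,
and averages recall over queries and then folds.  A class whose size
divided by k falls below `queries_per_class` is rejected by name.
Queries are drawn per fold; the per-fold seeds descend from one
`SeedSequence`, so the whole protocol is reproducible.

## Concordance statistics

Activity classes are judges, methods are the ranked objects.  Within a
judge, the largest recall receives rank n (so the best method has the
highest mean rank) and ties receive mid-ranks.  With rank sums R_i,
their mean m(n+1)/2 and squared-deviation sum δ,

    W = 12 δ / (m²(n³ − n) − m Σ_j T_j),   T_j = Σ (t³ − t),

which reduces to the plain coefficient on tie-free matrices.  Tie
correction is the default because published method tables contain tied
recall cells and the standard statistical tools apply it; an
uncorrected mode is available for comparison.  Significance uses the
chi-square approximation χ² = m(n−1)W on n−1 degrees of freedom, with
0.05 and 0.01 flags.  The improvement percentage between two methods
is 100·(r₁ − r₂)/r₁ and requires r₁ > 0.

A fully tied matrix (every judge ranks all methods equal) carries no
ranking information; `kendall_w` raises on it, and the pipeline skips
the concordance report for that cutoff with a log note.  `rank_report`
computes mean ranks directly so even degenerate tables still report.

## Problem sizes used in tests and reproduction

The statistical layer is exercised at full published scale (the
bundled tables).  The neural layer is exercised at reduced widths —
fingerprint length 128, branch width 128 or 64, 8 conv filters, a few
hundred training pairs, ≤ 8 epochs — sizes chosen so the whole suite
runs in seconds on one CPU while preserving every structural element
of the architectures (twin sharing, three measures, fusion, two
conv/pool stages, end-to-end hybrid training).  The easy two-class
configuration (within-class similarity 0.6 over a sparse background)
is the learnability benchmark: a trained scorer must separate held-out
same-class from different-class pairs.

## Known limitations

* Synthetic libraries capture count-vector statistics only, not
  chemistry; absolute recall values are not comparable to benchmark
  collections.
* At small library sizes recall@1% saturates at the cutoff size (one
  kept position per 100 molecules bounds recall by 1/actives), which
  can tie all methods at the ceiling; use larger libraries or the 5%
  cutoff when contrasting methods.
* The chi-square p-value is an approximation; no permutation-exact
  test is provided.
* Decision hybrids reuse independently trained components; no joint
  fine-tuning. Weight pruning of the hybrids is out of scope.
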