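# Methods

## Model

`noisecut` fits a two-layer tree functional network to labeled binary
data.  The structure — M first-layer boxes reading disjoint, contiguous
blocks of `n_1, …, n_M` feature columns — is supplied by the user as prior
knowledge and never learned.  Box inputs are addressed by the decimal
encoding `1 + Σ 2^(i−1) b_i` with the *first* column of a block as the
least-significant bit; all truth tables, serialized models and conflict
graphs use these 1-based codes.  Assumptions inherited from the model
class: features are binary, the label is binary, boxes share no features
(tree structure), and the network has exactly two layers.

## Learning

**Conflict graphs.**  For box m, every unordered pair of training samples
with different labels whose box codes agree on all boxes except m adds one
unit of weight between the pair's two codes in box m.  Pairs differing in
zero boxes (identical features, discordant labels — possible after noise
injection) or in two or more boxes contribute nothing; the former would be
self-loops that no bipartition can cut.  The builder groups rows by the
code tuple of the other boxes and accumulates an outer product of the
per-context label histograms, which is algebraically identical to the
naive pair scan (kept in the package as `build_weight_matrices_naive` and
compared in tests) but runs in roughly O(S·M + Σ contexts·4^n_m) instead
of O(S²).

**Max-cut.**  Each box function is the bipartition of the box's codes that
maximises the total weight of explained disagreements.  `solve_maxcut`
certifies optimality by one of two interchangeable exact routes:

* exhaustive enumeration for graphs of ≤ 20 vertices (vectorised,
  evaluating all 2^(n−1) partitions with vertex 1 fixed to side 0; ties
  broken toward the lexicographically smallest assignment);
* HiGHS branch-and-bound on the MILP edge model (binary side indicators
  `x_u`, edge variables `y_uv ≤ x_u + x_v`, `y_uv ≤ 2 − x_u − x_v`)
  otherwise.  The plain edge model has a vacuous LP relaxation (the bound
  equals the total weight), so the model is strengthened with the four
  triangle inequalities of every positive-edge triangle — valid for every
  cut, hence exactness-preserving — which makes 64-vertex conflict graphs
  at realistic noise levels solvable in seconds.  Symmetry is broken by
  fixing `x_1 = 0` (sound because complementing a cut preserves its
  value), edge variables stay continuous (with binary `x` they are forced
  to the cut indicator at the optimum), and a relative MIP gap below one
  weight unit is used as the stopping rule, which is exact for integer
  weights.

Each solve carries a wall-clock budget (default 120 s per box in the
model, 20 s in the sweep harness).  On exhaustion the solver **raises**;
it never returns an uncertified cut.  Dense quasi-random conflict graphs —
which arise for 5- and 6-input boxes when half the labels are flipped —
are beyond proof-of-optimality for any LP-based solver at this size, and
the sweep harness logs and skips such runs rather than degrade exactness.

**Orientation and the output box.**  A cut determines a box function only
up to complement.  The side containing code 1 (the all-zero input) is
labeled 0, making fits reproducible; the output box absorbs the choice, as
the orientation-invariance test verifies.  Vertices untouched by any edge
(codes with no conflicting evidence) land on side 0 deterministically.
The output box is identified by majority voting over the training labels
routed to each of its 2^M input codes.  Cells with tied votes, and cells
no training sample reaches, receive the global training-majority label
(ties broken to 0) — the minimal-risk constant in the absence of evidence.
Vote counts are retained: `predict_score` reports the fraction of label-1
votes at the routed cell (training prevalence for unseen cells), which
thresholds back to the hard prediction at 0.5 and supplies a ranking score
for AUC-ROC.

## Synthetic benchmark generator

The generator emulates the benchmark study conditions: random two-layer
tree networks with three first-layer boxes of 2–6 inputs over d = 8–12
total features (six structures per dimension, 30 networks in the full
suite).  Box-size compositions are drawn uniformly over the valid
compositions by rejection; truth-table entries are i.i.d. fair coin flips;
whole networks are redrawn (up to `max_retries`) until the class-1
fraction of the full enumeration lies in [0.1875, 0.8125], mixing balanced
and imbalanced labelings.  Datasets are **complete enumerations** of
{0,1}^d: every input appears exactly once, so d = 8–12 gives S = 256–4096
samples, the stated class-ratio bounds are exact dyadic fractions, and a
70% training split densely covers the input space — the regime in which
noise-free recovery is provably exact.  What the generator does *not*
emulate about real data: sampled (non-exhaustive, possibly duplicated)
inputs, feature noise, class-conditional label noise, and uncertainty in
the assumed structure.  Passing tests therefore demonstrate noise-tolerant
recovery under a correct prior and dense coverage, not robustness to a
misspecified structure.

Label noise flips the labels of ⌊qS + 0.5⌋ uniformly drawn samples of the
*full* dataset before the 70/30 split, and test metrics are computed
against the (possibly noisy) test labels; with a perfectly recovered
function the expected test accuracy is then 1 − q, which is the pattern
the benchmark medians follow.  Splitting is a plain uniform partition with
⌊0.7·S + 0.5⌋ training rows, not stratified.

## Noise-sweep harness

`run_noise_sweep` executes dataset × noise level × repeat runs.  Each run
derives a noise seed and a split seed from the master seed through
`SeedSequence(master, spawn_key=(dataset, noise_index, repeat))`, so runs
are reproducible individually and collectively, and repeats differ in both
the noise realization and the split.  Aggregates are medians with 95%
bootstrap percentile confidence intervals (2000 resamples, seeded); the
bootstrap is used because the sampling distribution of a median over a
handful of bounded accuracies has no convenient closed form.  Failed runs
(solver budget exhaustion) are logged with their coordinates and excluded
from the medians.

## Problem sizes and numerical choices

The reduced benchmark used by the acceptance script — d ∈ {8, 9, 10}, two
structures per dimension, three repeats, noise {0, 2.5, 5, 7.5, 10, 50}% —
aggregates 18 runs per noise level and reproduces the full-scale medians
to well within the run-to-run spread; the full 30-dataset, five-repeat
protocol is available through `noisecut sweep` defaults.  Enumeration is
guarded at 2^24 rows.  The brute-force solver is capped at 20 vertices
(2^19 partitions per chunked evaluation).  Metrics with empty
denominators (e.g. recall without positive test samples) are reported as
0 with an `undefined` flag rather than raising, keeping sweep rows
machine-readable.

## Known limitations

* The feature-to-box mapping is fixed to contiguous column blocks in the
  order of `n_input_each_box`; permute columns beforehand if the prior
  knowledge groups non-adjacent features.
* Only binary labels and binary features are supported; only two-layer
  tree structures (no shared features between boxes).
* Proving max-cut optimality on dense 32–64-vertex conflict graphs at
  extreme noise (≈50% flips) exceeds LP-based branch-and-bound; such runs
  abort cleanly under the time budget.  At the benchmark's headline noise
  range (0–10%) all instances solve in seconds.
* Exactness of recovery requires dense coverage of each box's input codes
  in every context; sparse real-world designs weaken the conflict-graph
  evidence and the guarantees degrade gracefully to majority behaviour.
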