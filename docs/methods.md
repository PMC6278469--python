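# Methods

`efolearn` trains sparse linear scoring models for binary classification on
numeric descriptor tables by maximizing a ranking-quality objective rather
than a likelihood.  It is designed for the regime where the positive class is
rare (order 10–15%) and where the features are raw physicochemical
descriptors spanning wildly different magnitudes — the setting of
reactive-metabolite substrate prediction, where standard classifiers degrade
on the unbalanced labels and where a score (not just a binary call) is
wanted for each prediction.

## Model family

A model is a linear combination of k named descriptors,

    score(x) = c1·v1 + c2·v2 + … + ck·vk ,

with no intercept: rankings are translation-invariant, so a constant term is
unidentifiable and excluded.  By convention the leading coefficient is
normalized to ±1 (dividing all coefficients — and the threshold — by |c1|,
a positive factor that changes no ranking or thresholded class).  This fixes
the scale degeneracy of rank-based objectives and matches how such equations
are conventionally printed.  Features are consumed raw; no scaling,
weighting or normalization is applied anywhere in the pipeline.

## Quality function

Given a training table with t instances and n positives, a candidate
coefficient vector induces a descending ranking (ties broken by input row
order, so results are reproducible).  The ranking is cut into consecutive
clusters of a user-set size (default: n, the positive count), and the
positive percentage RMᵢ of each cluster is recorded relative to that
cluster's actual size (the last cluster may be smaller).  The objective is

    Quality = AI × RM₁ ,

where RM₁ is the first cluster's positive percentage (early recognition)
and AI, the asymmetry index, is Pearson's moment coefficient of skewness of
the cluster profile,

    AI = m₃ / m₂^{3/2},   m₂, m₃ population moments of {RMᵢ},

rewarding profiles whose positives decay from the front of the ranking.
A flat profile has zero variance; its skewness is undefined, and we define
AI = 0 there so uninformative models score worst.  Note that moment skewness
of a palindromic profile is *not* zero (e.g. [10, 20, 10] has positive
skew); only profiles symmetric about their mean have AI = 0.

## Fitting pipeline

1. **Filtering.**  Each descriptor is used alone as a score, in both
   directions, and its best top-5% enrichment factor (EF) is computed:
   EF = (positive rate in the top 5% of the ranking) / (overall positive
   rate).  Descriptors are kept iff this EF strictly exceeds a cut-off
   (default 2.0).  Constant descriptors are always discarded.  A cut-off of
   0 disables the filter.  The EF ceiling for a prefix of m instances is
   min(m, P)·N/(m·P): on a balanced dataset it is 2.0, so the default
   cut-off is unattainable there and the filter must be smoothed (1.5, 1.0)
   or removed.
2. **Combination.**  All C(m, k) variable sets of the m kept descriptors
   are enumerated when that count is at most `max_combinations` (default
   20000).  Beyond it, a greedy forward search runs: the best
   `n_models_kept` variable sets of size j, ranked by training quality, are
   each extended by every unused descriptor to size j+1, from j = 1 up to
   k.  This mirrors staged search on a reduced descriptor file and keeps
   the cost linear in k instead of combinatorial.
3. **Coefficient optimization.**  For each variable set, 12·k random start
   vectors (coordinates uniform on [−1, 1], divided by each variable's
   sample standard deviation so raw descriptors contribute comparable
   initial score terms) are scored; full Hooke–Jeeves pattern searches run
   from the best 3 of them and the best terminal point wins.  The pattern
   search uses exploratory ±step moves per axis with pattern
   extrapolation; the initial step is 0.25·|x₀ⱼ| (floor 0.1), every failed
   exploration halves all steps, and the search stops when the RMS of the
   step vector drops below 0.001 or after 5000 iterations (budget
   exhaustion is a flagged, normal termination).  The objective is
   piecewise constant — it changes only when two instances swap rank — so a
   derivative-free method is required, and improvements are demanded
   strictly (>) so plateaus terminate.
4. **Threshold.**  The score of the rank-n training instance becomes the
   classification threshold; prediction uses score ≥ threshold (the
   boundary instance itself is positive).  On training data this predicts
   exactly n positives, up to ties at the threshold.
5. **Probabilities.**  The training ranking is cut into consecutive
   percentile bins (default width 2% of the instances); each bin's positive
   fraction is the predicted probability for any new score falling in that
   bin, with out-of-range scores clamped to the extreme bins.  The bin
   width is configurable (`bin_fraction`).

All randomness flows from one seed; fits are deterministic given (table,
config, seed).

## Validation protocol

`make_splits` draws plain (non-stratified) random 70/30 splits, repeated 5
times by default; a split whose learning half lacks either class is
resampled.  `evaluate_split` fits on the learning half only (cluster size
defaulting to the learning-set positive count), then classifies the test
half with the training-derived threshold: the number of test instances
scoring at or above it cuts the test ranking into predicted positives and
negatives, from which the confusion matrix and precision / accuracy / MCC /
sensitivity / specificity follow, alongside test-ranking EF at the top 1%
and 10%.  `calibration_sweep` refits on the full table per setting (no
split) and tabulates the mean top-1% and top-10% positive counts over the
kept models plus the best top-10% count; counts (not percentages) are
averaged, reported to one decimal.

Because sensitivity equals the first cluster's positive fraction only when
the cluster size equals the positive count, evaluation reports carry a
separate `top_cluster_positive_fraction` field rather than conflating the
two.

## Synthetic data

The generator emulates the statistical shape of a curated
metabolic-substrate descriptor table: 977 instances × 28 descriptors with
138 positives (14.1%) by default, plus a balanced mode for UCI-like shapes
(270×13, 208×60, ~50% positive).  Descriptors are independent Gaussians
multiplied by per-descriptor scales drawn log-uniformly over four decades,
exercising the unscaled-data regime.  Six informative columns carry a
linear signal: the latent score is

    latent = effect_size · Σⱼ wⱼ zⱼ + η,   wⱼ ~ U(0.5, 1.5),  η ~ N(0, 1),

over the standardized informative columns, and the top-138 latent scores
are labeled positive before 2% of labels are flipped at random.
`effect_size` is therefore the average per-descriptor coefficient in SD
units against unit latent noise: 0 yields labels independent of the
descriptors (the null fixture), 1 gives each planted descriptor a
one-standard-deviation pull.  Labels-by-thresholding (rather than logistic
sampling) puts the ground truth inside the learner's own model family, so
parameter recovery is sharply assertable.

What the generator does *not* emulate: correlated descriptors (real
physicochemical descriptors are collinear even after pruning), non-Gaussian
marginals, and any chemistry.  Passing recovery tests therefore demonstrate
the machinery — filtering, search, optimization, thresholding — not
performance on real molecules.

A consequence of signal dilution worth knowing: a single informative
column's correlation with the latent score saturates at wⱼ/‖w‖ as the
effect grows, so with six planted columns a weak-weight column can sit
below the single-descriptor EF filter ceiling no matter how strong the
overall signal.  On the default fixture the per-column top-5% EF lands near
2, so the recovery protocol smooths the filter cut-off to 1.5 — the same
remedy used for balanced data — keeping the planted columns (EF ≈ 1.7–3)
while still discarding most noise columns.

## Problem sizes used in the shipped checks

Planted-signal recovery runs the full default fixture (977×28) for one
70/30 split on each of three seeds with k = 6 and cut-off 1.5.  The null
calibration runs five splits of a 400×12 null table (effect 0, filter off,
k = 3, 5 models kept): null behaviour — held-out MCC centred on zero — does
not depend on the table's size, and this shape keeps the five refits quick.
Other tests use 150–200-instance fixtures with reduced optimizer budgets
(`hj_iterations` 100–300), which are config parameters, not code paths.

## Numerical choices and degenerate inputs

* Tied scores: stable sort on input row order.
* Prefix size for a top fraction f: round(f·N), half away from zero,
  floored at 1.
* Zero-variance cluster profile: AI = 0 (and hence quality 0).
* 0/0 in a classification metric: reported as 0 and flagged in the
  report's `degenerate` set, never raised, so sweeps stay total.
* EF is undefined (raises) when a ranking has no positives.
* A leading coefficient within 1e-12 of 0 after optimization rotates the
  largest-magnitude coefficient to the front before normalizing; a fully
  degenerate all-zero optimum falls back to a unit leading coefficient
  (both logged).
* Model JSON round-trips exactly (floats serialized by repr); a loaded
  model whose leading coefficient is not ±1 is renormalized with a warning.
* Missing values anywhere are an error naming the offending row and
  column; nothing is imputed.

## Known limitations

* Model selection by training quality among many variable subsets
  overfits: held-out MCC of the single best model runs noticeably below
  the best model in the kept list on moderate-signal data.  The full kept
  list (`n_models_kept`, default 20) with per-model test reports is the
  intended consumption; selecting on a validation metric is left to the
  user.
* The greedy fallback explores a thin slice of the combination lattice and
  can miss variable sets whose value only appears jointly.
* Probability estimates are raw bin frequencies without shrinkage; with a
  2% bin on a few hundred training instances each bin holds only a handful
  of instances and the fractions are noisy.
* Binary labels only; no multi-class, no nonlinear terms.
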