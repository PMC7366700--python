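# Methods

## Model and assumptions

The package refines a sparse bipartite table of pairwise prediction scores
(entity_a × entity_b → [0, 1]) under one structural assumption: score
distributions are heterogeneous *per entity*, so the evidence a score
carries depends on where it falls within the two One-to-All (O2A)
distributions it belongs to, not on its absolute value. The cascade
therefore (1) locates a local decision threshold per entity, (2) re-expresses
every pair as context features relative to its two thresholds, and
(3) learns a classifier on validated positives versus sampled unvalidated
pairs. The semi-supervised caveat is inherited: "negatives" are unvalidated
pairs, a small fraction of which may be true interactions; uniform sampling
keeps that contamination unbiased.

## O2A curves and percentile ranks

Curves are sorted by descending score with ties broken by partner id, so
construction is deterministic. Rank k (1-based) maps to percentile
(k−1)/(n−1); tied score blocks share their mean percentile; a single-point
curve gets 0.5. This convention makes rank features comparable across
curves of different sizes and invariant under strictly monotone score
transforms (asserted by property tests).

## Baseline estimation

- **Dense curves (n > 100):** LOESS (locally weighted linear regression
  over normalized rank, default span 0.3) smooths the curve, then Kneedle
  locates the knee. Robustness reweighting is disabled (`it=0`): on a
  monotone rank curve the short head is systematically flagged as outliers
  and the fit collapses onto the tail line, erasing the knee.
- **Kneedle:** both axes are min-max normalized; the difference curve
  d = chord − y is formed (the chord runs corner to corner of the unit
  square); the first local maximum of d exceeding the sensitivity-adjusted
  threshold S·mean(Δx) (S = 1 by default) is the knee. A straight line has
  d ≡ 0 and returns no knee. This simplified acceptance rule (rather than
  the original drop-below-threshold scan) is exact for the monotone,
  few-candidate curves that arise here.
- **Knee refinement:** smoothing rounds a sharp corner and drags the
  maximum of d a fraction of the smoothing window toward the tail. The
  knee rank is therefore refined as the argmax of the raw-curve difference
  curve within one window of the smoothed estimate, and the cutoff score
  is read from the raw curve at that rank (the smoothed value is a fit
  artifact). On noise-free planted two-slope curves this recovers the
  breakpoint exactly; additive noise on a gentle tail degrades precision
  roughly as noise divided by tail slope.
- **Sparse curves (n ≤ 100), and dense curves with no qualifying knee:**
  the median of the scores. Even-n median is the mean of the central pair;
  the cutoff percentile is that of the point nearest the median, with ties
  (the central pair is always equidistant) resolved to the lower rank
  under an explicit tolerance so the choice is stable under monotone
  transforms and floating-point rounding. The fallback guarantees every
  entity has a baseline. On sigmoid-shaped random curves a substantial
  fraction of dense curves is genuinely kneeless (concave or near-linear)
  and correctly falls back.
- Mean and population standard deviation (n divisor; sd = 0 for n = 1) of
  each curve are recorded for the standard-score features.

## RP features

The 14 model inputs are the raw score plus 13 context features (README
table). Design choices where the definitions were open:

- **ARRO** = (1−rxy)(1−ryx), so 1 means uniquely top-ranked from both
  perspectives and the feature lives in [0, 1].
- **Fold differences** are relative differences from the local cutoff
  score with an ε = 1e−6 guarded denominator; positive = above threshold.
- **Percentile margins** are signed as cutoff minus rank, so positive =
  better than the local threshold.
- Binary above-global/local-threshold indicators are deliberately omitted:
  the raw score lets the model learn any global threshold, and the fold
  differences carry the local information in graded form.

## Dataset assembly and training

Positives split into train/test by recency tag (or a seeded fraction when
untagged). Negatives are sampled uniformly without replacement from scored
unvalidated pairs, *separately per partition* with the test draw excluded
from the train pool, which guarantees train/test disjointness. Balance
(|neg| = |pos|) is on by default.

Model defaults are fixed at the tuned values: gradient boosting with
learning rate 0.3, γ = 0, depth 6, 200 rounds, early stopping 5 on a
seeded 10% validation carve-out of the training rows (the early-stopping
mechanism requires one; stratified refit if a class is missing); random
forest with 100 trees, depth 19, and an absolute cap of 4 candidate
features per split. Single-threaded deterministic fits; the fitted model
serializes with schema, config and seed embedded and refuses to predict on
a mismatched schema.

## Evaluation

ROC AUC is trapezoidal (equivalently the normalized Mann–Whitney U with
half-credit ties — asserted against an O(n²) oracle); PR AUC defaults to
the stepwise precision convention (average precision) with a trapezoid
option, since the convention materially changes values. Bootstrap
resampling is stratified within class (both classes always present) and
*paired*: one index draw per iteration scores all models, and Welch's
unequal-variances t-test compares the resulting AUC vectors. The printed
λ-weighted combined score s = (1−λ)·m·λ·r is implemented verbatim; its
weights cancel to a positive scalar, so the ranking is λ-invariant on
(0, 1) — documented and asserted rather than hidden. Tiers are cumulative
top-k sets with boundary counts ceil(f·N), innermost label reported.

## Synthetic study conditions

The generator emulates a sparse integrative score table: 60 × 400 entities
at density 0.6 (~14,400 pairs), chosen so the A axis produces dense
(n > 100) curves and the B axis sparse (n ≤ 100) curves, exercising both
baseline branches. Each entity draws a latent offset ~ Normal(0, 1.5) on
the logit scale; 10% of scored pairs are planted positive with a +2.0
logit lift; observation noise is Normal(0, 0.5); scores are the logistic
transform, clipped to (0, 1). The offsets are the mechanism that defeats a
global threshold and makes local context informative — with
baseline_spread = 0 the raw score is near-optimal and the cascade adds
nothing (asserted as a control). 15% of positives carry the `test_recent`
tag: a real recency split holds out a few percent of a huge label set, but
at desk scale that fraction would leave too few hold-out rows for a stable
bootstrap, so the tagged fraction was set once to yield ~400 balanced test
rows. `knee_frac` parametrizes the planted head fraction for the
two-slope knee-recovery curves.

What the generator does **not** emulate: sequence-level structure (seed
matches, binding energies), correlated predictor errors, non-uniform
label-validation bias, and the ~41M-pair scale of real integrated score
tables. Passing tests therefore demonstrate that the implementation
recovers planted reciprocal structure and is internally consistent — not
that the gains transfer at full scale to real data.

## Numerical choices and degenerate inputs

Scores must already be in [0, 1] (optional clipping); duplicate score rows
are an error by default or resolved keep-max. Empty views, single-class
labels, NaN features, constant-score test sets and λ outside [0, 1] raise
informative errors. All sampling flows through `numpy.random.default_rng`
with explicit seeds; fixed seeds make the entire features → train →
predict path byte-reproducible.

## Known limitations

- Kneedle's knee index is exactly invariant under affine score maps but
  not under general monotone transforms (curvature changes); rank-feature
  invariance under monotone transforms holds for median-based baselines.
- The fold-difference and ARRO definitions are documented interpretations
  of underspecified quantities; both are centralized and switchable.
- Gene-side-only label filtering follows the miRNA-target setting; a
  `symmetric` flag serves other domains.
- Problem sizes in tests and the acceptance script (60 × 400 table, 200
  bootstrap iterations, 50 knee curves, 400 null replicates) are the
  package's desk-scale study conditions; statistics at this scale carry
  wider error bars than full-scale runs.
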