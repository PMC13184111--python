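# Methods

This note documents the model, the numerical choices, and the synthetic
evaluation conditions implemented in `fcmdss`, including the points where
the design was genuinely open and a choice had to be fixed.

## Model and assumptions

An FCM classifier over `n = d + 1` concepts is parameterized by a weight
matrix `W ∈ Ω = [−1, 1]^{n×n}` restricted to a binary topology mask `M`, a
scalar output bias `b`, and a sigmoid steepness `λ > 0`.  Orientation
convention: `w[i, j]` is the influence of concept `i` (row) on concept `j`
(column); activations are row vectors and free dynamics propagate as
`A ← f(A·W)`.  This convention is load-bearing: it is what reproduces the
worked example's pre-activation `[0, 0.24, 0.68]` from `[0.80, 0.60, 0]`.

Two reasoning modes exist.  *Free* mode updates every concept and is used
for dynamics diagnostics.  *Clamped* mode — the classification mode — holds
the `d` fuzzified feature concepts fixed and iterates only the output node,
so the inner loop is a scalar fixed-point iteration per sample with constant
drive `u = Σ φᵢ w_{i,n} + b`.

The sigmoid is treated as a map `ℝ → (0, 1)`.  Negative pre-activations
arise whenever weights are negative, so restricting the domain to
nonnegative inputs would be incoherent with the admissible weight box.

**Contraction regime.**  The package targets the fixed-point regime only
(no limit cycles or chaotic itineraries, which FCM dynamics can exhibit for
large `λ‖W‖`).  With `L_f = λ/4` the inner map contracts whenever
`L_f·‖W‖ < 1` for an operator-compatible matrix norm.  `contraction_report`
defaults to the spectral norm — the operator norm induced by the Euclidean
vector norm, which the contraction argument requires to be submultiplicative
— with Frobenius and max-row-sum selectable.  The inner stopping rule uses
the max (infinity) vector norm on successive differences; the outer stopping
rule uses the Frobenius norm on weight changes.  Both choices are fixed here
because reproducibility requires naming them, not because the alternatives
fail.

## Fuzzification

All preprocessing statistics are functions of the training partition only:
min/max for normalization, medians/modes for imputation, category risk
rates, and point-biserial initial weights.  Imputation happens before
normalization.  Decisions taken where the procedure was underdetermined:

* Out-of-range values in held-out data are clamped to `[0, 1]` after
  normalization, keeping membership inputs inside the fitted domain.
* A constant training feature normalizes to 0.5 everywhere (uninformative
  middle).
* "Smoothed" categorical positive rates use Laplace add-one smoothing,
  `p̂ = (k + 1)/(m + 2)`, before rescaling across categories with the
  `ε₀ = 1e-8` guard.
* Risk orientation (`higher_is_risk` / `lower_is_risk`) is declared per
  feature in configuration.  It encodes clinical knowledge; the package
  deliberately does not infer it from data.
* The packaged cardiovascular membership table (six continuous/ordinal
  features, three states each) is shipped as printed values rather than
  re-derived from terciles.
* The initial bias is 0 (no prior pull toward either class).

The initial graph is a star: every feature concept feeds the diagnostic
node, the diagnostic node has a self-memory edge of 0.20, and feature edges
start at `clamp(|ρ(φᵢ, y)|, 0.05, 0.90)`.  The floor keeps all permitted
edges alive for learning; the cap keeps the prior well inside the
contraction-friendly range.

## Learning

The objective is mean (optionally class-weighted) cross-entropy plus
`β‖W‖_F²`.  The penalty excludes the bias: the interpretability machinery
scores edge weights only, and shrinking `b` would just recenter the
operating threshold.

Gradients backpropagate through *all executed* inner iterations — to
convergence or the iteration cap — with no additional truncation window.
In clamped mode this reduces to two scalar recursions per sample
(sensitivities to the in-edges/bias and to the self-edge), vectorized over
the batch; free mode unrolls the full state trajectory per sample.
Numerical guards: predictions are clipped to `[1e-12, 1 − 1e-12]` inside the
log loss; the gradient is rescaled to Frobenius norm ≤ 1 (clip level
configurable), with the bias gradient scaled by the same factor so clipping
preserves the joint direction.  A non-finite objective aborts training with
the offending state.

The outer step projects onto the box, re-zeroes masked entries, and — when
expert feedback is present — convexly blends with the reference matrix.
Both feedback forms are implemented: *edgewise* (only reviewed edges move
toward recommended values; others pass through) and *reference-matrix* (the
whole candidate is blended toward a full matrix; the benchmark reference is
the initial prior `W⁽⁰⁾`).  Feedback applies every outer iteration with a
constant `α`; a schedule hook exists but defaults to constant.  The loop
stops at Frobenius weight change ≤ δ = 1e-4 or after `max_outer = 150`
iterations (no cap is prescribed anywhere; 150 is an order of magnitude
above the ~10 iterations the blended map typically needs at δ = 1e-4).

For convergence diagnostics, `train` accepts an injected gradient/objective
pair in place of the FCM forward pass.  The injected gradient is used as
supplied (apart from clipping), which is what lets the test suite verify
the predicted `(1−α)·max(|1−ημ|, |1−ηL_J|)` contraction factor on a
strongly convex quadratic with a known fixed point.

Batch forward passes run all samples' scalar loops in lockstep and stop
when every sample's step difference is within tolerance; each sample thus
meets at least its own single-sample stopping rule, and `predict_sample`
(per-sample loop) agrees with the batch path to well below the tolerance.

## Threshold, metrics, and interpretability

`τ` is selected once, after training, by maximizing F1 on the validation
partition over the 17-point grid `{0.10, 0.15, …, 0.90}` (a smaller
4-point grid is selectable).  Ties go to the smallest `τ`, favoring
sensitivity — the conservative direction for a screening setting.
Zero-denominator precision/recall is reported as 0 with a warning.
`I_struct` counts active edges at the strict threshold `|w| > 0.05` and uses
strict sign equality with `sign(0) = 0`, so an active learned edge over a
zero prior counts as disagreement; with no active edge the score is
not-applicable (NaN), never silently 0 or 1.  Only the sign form of
structural agreement is computable; any richer "semantic role" judgement is
left to human review of the per-sample equilibrium activations.

## Synthetic scenarios

The cardiovascular generator draws eight features from the stated
Normal/Beta marginals (Normals clamped into `[0, 1]`; clamping rather than
rejection sampling, stated here because the truncation mechanism is
otherwise ambiguous), samples labels from
`p_cv = σ(1.40x₁ + 1.15x₂ + 0.90x₁x₃ + 0.55·log(1+x₄) + 0.40x₆ − 1.25)`,
then adds Gaussian observation noise (sd 0.03) and re-clamps.  Labels are
drawn *before* noise: one seed spawns three independent substreams
(features, labels, noise), so toggling noise never changes labels.  The
metabolic scenario mirrors this design with seven features and its own
coefficient set; its marginals are not pinned down anywhere, so the package
declares Normal/Beta defaults following the cardiovascular pattern and
leaves them overridable in `ScenarioSpec`.

What the generators emulate: graded risk factors on `[0, 1]`, a smooth
monotone-plus-interaction risk surface, Bernoulli diagnostic labels, mild
measurement noise.  What they do not emulate: measurement batch effects,
label noise, feature dependence beyond the single interaction terms,
informative missingness, or distribution shift.  Passing tests on these
scenarios therefore demonstrate correctness of the mechanics (recovery of
influence ordering, protocol integrity), not clinical performance.  Notably
the cardiovascular risk surface is weakly separable by construction: scoring
samples by their own generating probability yields AUROC ≈ 0.60, which
bounds every classifier on this scenario.

## Evaluation protocol

Repeated stratified 60:20:20 splits (largest-remainder allocation per
class), default 20 repeats, repeat `i` seeded by `base_seed + i`.
Preprocessing, tuning, and `τ` selection see only their designated
partitions; baselines (logistic regression, SVM, random forest, gradient
boosting, k-NN, MLP) enter through thin adapters over scikit-learn with the
declared validation grids and classify at 0.5 unless class-weighted.
Robustness conditions cross MCAR missingness {10 %, 20 %, 30 %} (injected
before imputation), training-only positive-class downsampling to ratios
{1:1, 1:2, 1:3}, and cost weights {(1,1), (1,2), (1,3)}.  Complexity is
accounted in multiply-accumulate counts per reasoning step (mask nonzeros),
not wall-clock time.

## Problem sizes used in the shipped checks

The test suite exercises dynamics on graphs of 2–6 concepts, learning on
10–40-sample toys, and the recovery check on the full N = 2000
cardiovascular scenario across 5 seeds with a 60:20:20 split; protocol
tests use 2–3 repeats on a few hundred samples.  These sizes make the whole
suite run in seconds while still covering every code path at the scales the
method is specified for.

## Known limitations

* Only binary targets and a single diagnostic node are supported.
* The contraction guarantees are sufficient conditions; training does not
  enforce `‖W‖ < 1/L_f`, it only diagnoses it.
* The smoothness/strong-convexity constants of the outer analysis are never
  estimated from real objectives — they are exercised only in constructed
  quadratic oracles.
* The expert star mask is the benchmark topology; richer clinical masks
  must be supplied by the user through the JSON graph format.
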