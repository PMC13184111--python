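# fcmdss — expert-editable fuzzy-cognitive-map decision support

`fcmdss` implements a concept-level classifier for clinical tabular data
built on fuzzy cognitive maps (FCMs).  It is aimed at biostatisticians and
clinical-ML researchers who need a predictive model whose internal structure
a physician can read, audit, and *edit*: every learned quantity is a signed
influence weight between named clinical concepts, and expert corrections
enter the training loop as a bounded, convex operation rather than a hard
override.

## The model

A diagnosis problem with `d` predictive features becomes a graph of
`n = d + 1` concepts: `d` feature-risk concepts plus one diagnostic output
node.  Edge weights `W ∈ [−1, 1]^{n×n}` live on a fixed binary topology mask
`M` (benchmark: a star — every feature feeds the output node, which also has
a self-memory edge `w_nn = 0.20`).

**Fuzzification.**  Numeric features are min-max normalized with training
statistics, `z = (x − x_min)/(x_max − x_min)`, then mapped through Gaussian
linguistic states `μ(z) = exp(−(z − c)²/2σ²)` (Low/Medium/High centers
0.15/0.50/0.85, σ = 0.18 by default); the risk orientation of each feature
picks the High or Low state as the concept activation `φ ∈ [0, 1]`.
Categorical features are encoded as rescaled Laplace-smoothed positive-class
rates.

**Reasoning.**  For a sample with activations `φ`, the clamped inner loop
iterates only the output node to a fixed point,

    a ← f(Σᵢ φᵢ w_{i,n} + a·w_{n,n} + b),   f(t) = 1/(1 + e^{−λt}),

and the equilibrium activation `ŷ = a*` is thresholded at a
validation-selected `τ` for the binary decision.  Since `f` has Lipschitz
constant `L_f = λ/4`, any weight matrix with `‖W‖ < 1/L_f` (norm bound 4 at
λ = 1) makes the inner map a contraction with a unique equilibrium —
`contraction_report` checks this sufficient condition.

**Learning with expert correction.**  Weights minimize the regularized
cross-entropy `J(W, b) = mean CE(ŷ, y) + β‖W‖_F²` by projected gradient
descent, with `∂ŷ/∂W` obtained by backpropagation through the executed inner
iterations and the gradient clipped at Frobenius norm 1.  Each outer step is
then blended with an expert reference matrix `W_E`:

    W ← Proj_{[−1,1]}( (1−α)·Proj_{[−1,1]}(W − η∇J) + α·W_E ),   0 ≤ α < 1.

Under strong convexity this combined map contracts at factor
`(1−α)·max(|1−ημ|, |1−ηL_J|)`, so expert input accelerates and anchors
convergence instead of destabilizing it.  `α = 0` recovers a purely
data-driven FCM; the benchmark reference is `W_E = W⁽⁰⁾`, the initial
point-biserial prior `w_{i,n} = clamp(|ρ(φᵢ, y)|, 0.05, 0.90)`.

Alongside predictive metrics the package reports the structural
interpretability score `I_struct` (fraction of active edges, `|w| > 0.05`,
whose sign agrees with the expert prior), adaptation speed (outer iterations
to weight-change ≤ δ = 1e-4), and a run-to-run stability indicator.

## Worked example

The three-concept illustration (High Blood Pressure → Chest Pain → Heart
Disease) is packaged and replayed by the CLI:

```text
$ fcmdss illustrate
Concepts: High Blood Pressure, Chest Pain, Heart Disease
Initial activation: [0.8, 0.6, 0.0]
Step 1 pre-activation: [0.0, 0.24, 0.68]
Step 1 state: [0.5, 0.56, 0.66]
Expert blend on edge (1, 2): (1-0.3)*0.60 + 0.3*0.80 = 0.66
Step 2 pre-activation: [0.0, 0.15, 0.57]
Step 2 state: [0.5, 0.54, 0.64]
Disease activation moves from 0.66 to 0.64; at threshold 0.60 the classification is positive.
```

One propagation step already activates the disease concept to 0.66: blood
pressure 0.80 contributes `0.80·0.40` and chest pain 0.60 contributes
`0.60·0.60` to the pre-activation 0.68, and `f(0.68) ≈ 0.66`.  A physician
who judges the chest-pain influence 0.60 too weak recommends 0.80; with
blend share α = 0.3 the edge becomes 0.66 — between the data value and the
recommendation, never a hard overwrite.

An end-to-end synthetic run:

```text
$ fcmdss simulate --scenario cardiovascular --n 2000 --seed 7 --out cv.csv
wrote 2000 samples to cv.csv
$ fcmdss train --data cv.csv --outdir model/
trained in 9 outer iterations (converged=True); artifacts in model/
```

The training trace in `model/result.json` shows the objective falling from
0.6330 to 0.6288 with adaptation speed 9 (outer iterations to reach the
δ = 1e-4 stopping norm) — the expert blend pulls the iterates to their fixed
point quickly, keeping the learned map close to the clinically seeded prior.

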