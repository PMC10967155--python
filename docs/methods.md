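# Methods

This note documents the models, the solver, the synthetic-data generators and
the numerical choices behind `dsccn`, including the decisions that were
genuinely open and the limitations of what the tests demonstrate.

## Differential-expression stage

Per omics, every feature is compared between a disease and a healthy cohort
with a two-sided two-sample t-test and a fold change FC = mean(disease) /
mean(healthy) computed on the raw (positive) expression scale.  A feature is
called *low* iff p < 0.01 and FC < 0.5, *high* iff p < 0.01 and FC > 1, and
*normal* otherwise; the DE set is the union of low and high calls.

Choices:

* **Welch (unequal-variance) t-test.**  The cohorts this stage targets are
  strongly unbalanced (hundreds of tumors vs tens of normals), where the
  pooled-variance test is anti-conservative; Welch is the safe default.
* **FC as a ratio of arithmetic group means.**  The thresholds 0.5 and 1 are
  ratio-scale values, so the filter is only meaningful on a positive raw
  scale; the preconditions enforce a positive control mean.
* **The asymmetric dead zone is intentional.**  With fc_low = 0.5 and
  fc_high = 1, a feature with FC = 0.9 is never DE while FC = 1.01 with
  p < 0.01 is "high".  The rule is implemented exactly as stated; both cut
  points are parameters (`de_fc_low`, `de_fc_high`) for users who prefer a
  symmetric rule such as (0.5, 2).
* **No multiple-testing correction** — the stage is a filter, not an
  inferential claim; the raw p < 0.01 rule is used as given.  Features with
  an undefined t statistic (zero variance in both groups, equal means) get
  p = 1 and a warning.

## Sparse CCA with fused and graph-guided penalties

On column-centered, unit-norm matrices X (s×m) and Y (s×n):

    min_{u,v} −uᵀXᵀYv + γ₁ Σ_{k=1}^{m−1} ω_{k,k+1} √(u_k²+u_{k+1}²)
                       + γ₂ Σ_{(p,q)∈E} ω_{p,q} √(v_p²+v_q²)
    s.t. ‖Xu‖² ≤ 1, ‖Yv‖² ≤ 1.

The fused penalty ties adjacent mRNA features; the graph-guided penalty ties
methylation features connected in an undirected graph G.  When no graph is
supplied the complete graph is used (the incidence construction with
n·(n−1) ordered rows), which reduces the penalty to a data-driven group
shrinkage; a user-supplied adjacency (or edge list) overrides it.

### Solver

Alternating block minimization with iterative reweighting:

1. With v and the current weights fixed, the u-step minimizes a quadratic
   objective −bᵀu + uᵀdiag(d)u (b = XᵀYv; d collects γ·ω sums per
   coordinate) under the single quadratic constraint uᵀXᵀXu ≤ 1.  Its KKT
   system is `(2 diag(d) + 2λ XᵀX) u = b`; the constraint residual is
   strictly decreasing in the multiplier λ, so the active-constraint root is
   found by Brent's method after bracketing (with closed forms for the
   interior case and for the fully unpenalized case).  This is an exact
   solution of the constrained quadratic program — no iterative QP solver
   with its own tolerance is involved.
2. The v-step is symmetric.
3. Weights are refreshed from the new iterate:
   ω = 1 / (2√(a² + b² + ε)) with ε = 1e−6 (default, `reweighted` mode).
   This is the standard majorize–minimize reweighting for group penalties:
   the weighted quadratic surrogate touches the ε-smoothed penalty at the
   current iterate and dominates it elsewhere, so the recorded objective
   history (bilinear term plus ε-smoothed penalties) is non-increasing — an
   invariant asserted in the tests.  A `paper` mode with the literal rule
   ω_{k,k+1} = u_k² is retained for fidelity experiments; it does not
   majorize the penalty and carries no monotonicity guarantee.

Iteration stops when the relative objective change falls below `tol`
(default 1e−5) or after `max_iter` rounds; non-convergence is reported via a
flag, not an exception.  An all-zero solution (which occurs when the
penalties exceed the achievable bilinear reward — the constraint set always
contains the origin) is flagged degenerate.

Initialization is the uniform vector scaled to the constraint boundary,
making the default fully deterministic.  With γ₁ = γ₂ = 0 the alternation is
exactly the power iteration for the first classical canonical pair, which the
tests verify against an independent whitened-SVD CCA oracle (cosine ≥ 0.999).

### Model selection and feature selection

γ₁, γ₂ are chosen on a grid by the held-out |corr(Xu, Yv)| after a random
70/30 sample split; column statistics are fitted on the training rows and
applied to the held-out rows.  Ties break toward the larger training
correlation, then the smaller γ₁+γ₂.  Degenerate fits score −∞.  The default
grid {0.01, 0.1, 1} spans the under- to over-penalized regimes at the scale
of unit-norm columns.  After refitting, the m₁/n₁ largest-|weight| features
per omics are selected (ties keep the lower index; defaults m₁ = n₁ = 200,
clipped to the available feature count in the pipeline).

## Multi-task attention network

For each omics j, one affine layer maps the selected feature vector to
N^j·D values reshaped into N^j module vectors of dimension D, followed by
the activation (ReLU by default).  Between two views the attention matrix is
the row-softmax of pairwise cosine similarities between module vectors; the
attended representation Att(M^j, M^o)ᵀ M^j lives in the other view's module
frame and is concatenated with the raw M^j before the per-view fully
connected head (hidden widths (128,) by default) that emits class
probabilities.  The loss is the sum over views of the cross-entropy,
averaged over samples; probabilities are clamped at 1e−12 inside the log.

Open points resolved as package choices:

* **Concatenation contents.**  The attended product is concatenated with the
  view's own raw modules, so switching attention off only removes the
  attended block — encoder parameter counts are unchanged, which makes the
  ablation comparison clean (asserted in tests).
* **Fusion of per-task outputs.**  Arithmetic mean of the task probability
  vectors (the least committal choice); `product` and `task<j>` fusion are
  config switches.
* **Activation and head depth** are unspecified upstream; ReLU and a single
  128-unit hidden layer are the defaults, both switchable.

Training uses Adam with decoupled weight decay (decay applied to weight
matrices only), batch size 32, and early stopping on an internal stratified
validation split (fraction 0.15): training stops once the validation loss
has not improved for `patience` epochs and the best-epoch weights are
restored.  The canonical hyperparameter search space —
N ∈ {16, 32, 64, 128}, learning rate ∈ {1e−4, 1e−5, 5e−6, 1e−6}, weight
decay ∈ {1e−3, 1e−4, 1e−5}, patience ∈ {50, 100, 200, 300} — is available to
`hyperparameter_search`; the package default learning rate is the standard
Adam default 1e−3, which converges in a few hundred epochs at desk scale.
Everything is float64 numpy with hand-derived backpropagation (including
through the cosine-softmax attention); the gradients are validated against
central finite differences to ~1e−7 relative error in the test suite.

## Evaluation

Binary metrics follow the contingency formulas (ACC, Precision, Recall, F1);
multi-class results are macro-averaged one-vs-rest values.  AUC is reported
for binary tasks only (a one-vs-rest macro AUC would be a different
quantity; the positive class for binary F1 defaults to the smaller class and
is overridable, since the convention is otherwise ambiguous).  Zero-division
cases define precision/F1 as 0 with a warning.  The CV protocol is
stratified k-fold (default 5) repeated (default 30) with partition seeds
`seed + r` per repeat — reproducible yet distinct — and the aggregate is the
mean of the retained per-fold values.  The selected-gene analysis computes
Pearson r and two-sided p (via the exact t transform of r) for every
cross-omics pair of top-weighted features, with significance at p < 1e−5.

## Synthetic data

The generators plant exactly the structure each stage assumes, with
exhaustive bookkeeping so recovery is measurable:

* **DE cohort** — log-normal expression (`2^(baseline + shift + noise)`,
  baselines Uniform(3, 8) on the log2 scale) with a ±`effect_log2fc` shift on
  randomly chosen high/low features.  Defaults (effect 2, noise sd 0.25,
  50/50 samples) give planted fold changes of ~4 and ~0.25, comfortably
  outside the call thresholds but with realistic sampling noise.
* **Canonical pair** — a shared standard-normal latent z drives the
  block-contiguous u-support of X with loadings Uniform(0.8, 1.2); a latent
  with correlation `latent_corr` to z drives the clique-aligned v-support of
  Y.  Off-support features are independent unit-variance noise, so no column
  is constant even at zero support noise.  The methylation feature space
  carries a planted block graph (cliques of 5 consecutive features) whose
  edge list exercises the graph-guided penalty.
* **Subtyped dataset** — class labels with configurable sizes (the default
  study condition mirrors an 87/31/284/126 imbalance over 528 samples) add
  ±`class_shift` mean shifts on the support features, with one random sign
  pattern per class *shared across the two omics* — subtype-specific
  methylation differences are mirrored in expression, which is what makes
  selected cross-omics gene pairs significantly correlated, as in real
  tumors.  A healthy cohort expresses the support features at a baseline
  lower by 2^2, so the DE stage retains essentially the planted supports.

What the generators do **not** emulate: beta-distributed methylation values,
batch effects, missingness, heavy-tailed expression noise, or correlated
background features.  Passing tests therefore demonstrate correctness of the
algorithms and recoverability of planted structure under clean conditions,
not clinical-grade performance on real cohorts.

## Problem sizes and determinism

The default verification problems are desk-scale: 500-feature DE cohorts,
a 300×(100+120) canonical pair, and a 528-sample end-to-end run with 120+100
features.  All randomness flows from explicit integer seeds (one RNG stream
per generator call; training seeds its initialization, batching and
validation split), so identical configurations reproduce identical outputs
bit for bit.

## Known limitations

* One canonical pair only; no deflation for further pairs.
* The complete default graph makes the v-penalty blind to real methylation
  topology; supplying a biological adjacency is recommended when available.
* The `paper` weight-update mode can oscillate; it exists for comparison,
  not production use.
* Large penalties drive the solution to the degenerate zero vector (the
  origin is always feasible); the grid search screens these out via the
  held-out correlation, but a single fixed large γ can fail with a
  diagnostic.
* Binary AUC for the plugin classifier requires the plugin to expose
  `predict_proba`.
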