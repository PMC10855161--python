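# Methods

`trustomics` implements a trustworthy late-fusion classifier for
multi-omics cohorts: per-omics co-expression graphs, a multi-level
graph-attention encoder per omics, Dirichlet evidence with explicit
subjective-logic uncertainty, and Dempster–Shafer combination across
omics. This note records the model, its assumptions, the parameters that
matter, and the design decisions taken where the design was genuinely
open.

## Preprocessing

Raw per-omics matrices (subjects × features) pass through a fixed chain:

1. **Low-signal filter** — drop features whose raw mean is exactly 0 and
   features with SD at or below a platform-specific cutoff (defaults: 0.1
   for mRNA, 0.001 for methylation beta values, 0 for miRNA; "0" still
   removes constants). "Mean exactly 0" is literal equality on the raw
   matrix, checked before any scaling.
2. **ANOVA preselection** — keep the `k` features with the largest one-way
   F statistic; ties break by input order so selection is deterministic.
3. **PCA diagnostic** — the fraction of variance on the first principal
   component of the standardized matrix should stay below 0.5; because no
   corrective action is canonical, this is a *gate*, not a transform. The
   `on_pca_fail` policy is `warn` (default), `reduce-k` (shrink `k` by 10%
   steps until the gate passes) or `abort`.
4. **[0, 1] scaling** — per-feature linear min–max map. A feature constant
   on the fit subjects maps to 0 with a warning.

Every statistic (means, SDs, F values, PCA, min/max) is fitted on training
subjects only and frozen; held-out subjects are transformed with the
frozen state and may legitimately land outside [0, 1]. The pipeline object
stores all fitted state, so leakage is excluded by construction (and a
test perturbs held-out rows and asserts the fitted parameters are
bit-identical).

## Co-expression networks and subject graphs

For each omics, the cohort-level signed weighted adjacency is

    A_ij = ((1 + r_ij) / 2) ** beta,

with `r_ij` the Pearson correlation of features i and j over training
subjects. The soft-thresholding power `beta` can be fixed (default 6) or
chosen as the smallest power in {1..12} whose connectivity distribution
reaches a scale-free fit R² ≥ 0.8 (the standard weighted co-expression
practice; the fit index is the squared log–log correlation of binned
connectivity vs frequency). `A` is binarized at a threshold (default
0.08, grid-searchable over 0.05–0.5) into a binary edge matrix `E`
(`A_ij ≥ threshold`, symmetric, zero diagonal). The grid search accepts
any scoring callable; the built-in default scores candidates by an edge-
density band (0.05–0.30), because the alternative — downstream validation
accuracy — requires a training closure that the caller can pass in when
the extra cost is warranted.

Each subject's graph shares `E` and carries that subject's scaled feature
values as node features: topology is cohort-level and frozen on training
subjects; only node features vary per subject. Isolated nodes are kept;
self-loops (added inside the encoder) let them propagate their own value.

## Multi-level attention encoder

One encoder per omics. A single attention head scores each edge as
`LeakyReLU(a^T [W_C h_i ‖ W_C h_j])` (negative slope 0.2), normalizes
scores over the neighborhood (self-loop included) by softmax, and
aggregates `ELU(Σ_j α_ij W_R h_j)`; `T` heads are concatenated. Two such
layers produce representations G1 and G2 from the raw node values G0, and
the subject embedding concatenates all three levels per node and flattens
across nodes — the flatten readout preserves node identity, which the
feature-ablation interpretation relies on; a mean-pool readout is
available in config. Whether the raw G0 values enter the fused vector
directly is toggleable (`include_level0`, default on).

The evidence head is two fully connected layers (ELU between) with a
softplus output, so per-class evidence `e ≥ 0` by construction. Each
encoder also carries a linear softmax readout of the fused embedding
whose cross-entropy trains the attention stack directly.

Library defaults are T=4 heads of width 8 with dropout 0.1 on the fused
embedding. Additionally, node features undergo masked-ratio augmentation
during training: each subject draws a masking rate uniformly from
[0, `input_dropout`] (default max 0.8) and has that fraction of node
features zeroed, *without* inverted rescaling — a zero is the scaled
minimum, the exact "signal
removed" state the masking-robustness protocol probes. This matters
mechanistically: without it the evidence heads treat heavily zeroed
inputs as out-of-distribution and emit *more* evidence as masking grows
(uncertainty falls); with it, a subject whose informative features are
gone is unclassifiable, the evidential loss is then minimized by
near-vacuous output, and test-time masking raises the uncertainty mass
the way a trustworthy model should.

## Evidence, uncertainty and fusion

Evidence maps to a subjective-logic opinion via `alpha = e + 1`,
`S = Σ alpha`, beliefs `b_k = e_k / S` and uncertainty mass `u = K / S`,
so `u + Σ b_k = 1` exactly. Two opinions combine by the reduced
Dempster–Shafer rule

    b_k^F = (b_k^1 b_k^2 + b_k^1 u^2 + b_k^2 u^1) / (1 − C)
    u^F   = u^1 u^2 / (1 − C),   C = Σ_{i≠j} b_i^1 b_j^2,

where C sums only cross-class belief products — the u-involving products
are compatible, not conflicting, so this is Dempster's rule restricted to
singleton-plus-Θ mass functions, and it is commutative and associative
(property-tested to 1e-9; the configured fusion order is therefore
immaterial up to floating point). Total conflict (C ≥ 1 − 1e-12) raises
an error rather than renormalizing silently; with softplus evidence u > 0
strictly, so it cannot occur in training. The fused opinion maps back to
evidence via `S = K / u`, `e_k = b_k S`; class probabilities are the
Dirichlet mean `alpha_k / S`, with argmax ties resolved to the smallest
class index.

The same formulas run on plain arrays (public opinion API) and on
autodiff tensors (training graph); a test pins the two paths together, so
gradients flow through the fusion into every encoder.

## Objective

Per sample and Dirichlet, the evidential cross-entropy is
`Σ_k y_k (ψ(S) − ψ(alpha_k))` (the exact Dirichlet expectation of the
categorical log loss; verified against quadrature and Monte Carlo). A KL
term `KL[Dir(α̃) ‖ Dir(1)]` with `α̃ = y + (1 − y) α` (true class reset
to 1, natural log throughout) penalizes evidence on wrong classes; its
weight warms up linearly, `λ_t = cap · min(1, epoch / horizon)` with cap 1
and horizon 50 by default, so early uninformed evidence is not
over-punished. The global objective adds, per batch: the fused-Dirichlet
loss, the per-omics Dirichlet losses, and γ-weighted (γ = 1) softmax
cross-entropy on each omics' linear readout. Terms are averaged over the
batch — the per-subject sum rescaled by a constant — for learning-rate
stability.

## Training

All tensor computation runs on an in-package reverse-mode autodiff core
(`trustomics.nn`) over numpy arrays; every primitive is checked against
central finite differences, and a composite encoder-plus-loss gradient
check agrees to ~1e-10 relative error. Optimization is full-batch Adam
(default lr 2e-2, weight decay 1e-4, up to 200 epochs) with early
stopping on validation accuracy (patience 25) and restoration of the best
checkpoint. With features compressed into [0, 1] the required weight
magnitudes are large relative to Glorot initialization, and learning
rates of order 1e-3 stall on desk-scale cohorts; 2e-2 converges in
60–130 epochs and is the default. Runs are deterministic given the config
seed (one seed stream drives initialization and dropout). A non-finite
loss aborts with the full loss breakdown in the message. Splits are
stratified 70/15/15 train/validation/test.

## Synthetic cohorts

The generator emulates the structure of three-block multi-omics cohorts
(mRNA, DNA methylation, miRNA): block-correlated Gaussian features
(equicorrelated modules, default 5 modules of 10 features at rho 0.5,
independent across modules, shared covariance across classes),
class-conditional mean shifts on a designated informative subset (default
10% of features per omics, shift 1.5 noise-SD, assigned round-robin to
classes and spread across modules so correlation structure and class
signal coexist), balanced labels, and one global seed split into
independent per-omics substreams (adding an omics never perturbs earlier
blocks). `signal_classes` restricts which classes an omics can
discriminate — the complementary-modalities setting in which fusion is
genuinely necessary. Defaults (n=300 subjects, K=3 classes, d=50 features
per omics, effect 1.5) are the conditions under which all end-to-end
properties are evaluated.

What the generator does **not** model: methylation beta-value
distributions (everything is Gaussian), count noise for miRNA, batch
effects, class-dependent covariance, or feature-level missingness.
Passing tests therefore demonstrate mechanism correctness and recovery of
planted structure, not performance on real cohorts.

Masking a modality (`mask_modality`) replaces a uniformly random
`floor(ratio · d)` feature columns with 0 — the scaled minimum, i.e. a
"signal removed" reading; the mask value is exposed rather than hidden
because zeroing is a choice, not a law.

## Interpretation

Feature importance is global ablation: zero one (already-scaled) feature
across all test subjects, re-run inference with the fitted model, record
the drop in F1 (binary) or macro F1 (multi-class). The graph topology is
untouched and nothing is refit. The readout whose drop defines importance
is configurable: the default scores a feature of omics m by the drop in
omics m's *own* classification (the argmax of its opinion), matching the
per-modality reporting of the top-biomarker tables; a `fused` scope
scores the drop in the fused prediction instead. The per-omics scope is
the identifiable one — the combination rule deliberately compensates for
a damaged modality, so the fused readout under-reports any feature whose
information a second omics also carries. Drops are signed — an ablation
that improves the metric ranks last — and features with identical drops
share a dense rank. Top-k reports walk distinct ranks in order; a tie
group larger than the remaining room is down-sampled uniformly under a
seed, so reports are reproducible.

## Evaluation design and problem sizes

End-to-end properties (tests and the acceptance script) run on the
default cohort (3 omics × 50 features, 300 subjects, 3 classes) with a
2-head × 4-hidden encoder, fused-level dropout off and weight decay off
(the masking augmentation already regularizes strongly at this scale),
over 5 training seeds — a full 5-seed battery stays within minutes on one
CPU while exercising every mechanism; the library defaults (4 × 8,
dropout 0.1, weight decay 1e-4) are for real use. Robustness curves
average 16 masking draws per ratio on top of the training seeds, because
which columns a draw masks (informative or null) dominates the
within-ratio variance.

Two evaluation cohorts are used deliberately:

* the **planted** cohort (all omics informative for all classes) measures
  signal recovery, the permuted-label chance control, biomarker recovery
  by ablation, and the uncertainty-vs-masking trend — removing features
  of a modality that informs every class genuinely removes knowledge, so
  its uncertainty mass must rise;
* the **complementary** cohort (each omics discriminates one class)
  measures the fusion benefit and the accuracy-reduction trend under
  masking — with fully redundant omics, masking one modality barely
  moves fused accuracy, so the reduction is only identifiable when
  modalities carry distinct information. Conversely, a masked
  class-specific subject there turns into a baseline the omics
  confidently assigns to "one of the other classes", so *its* mean
  uncertainty is not a monotone probe — hence the split.

## Known limitations

* Zero is an in-range value after [0, 1] scaling, so "masked" and "low
  expression" are indistinguishable to the encoder; uncertainty-vs-masking
  trends are accordingly noisy at low masking ratios.
* The conflict C of sequential fusion is reported for the final pairwise
  combination only.
* Multi-class AUC is intentionally not reported; binary AUC uses the
  fused Dirichlet-mean probability of the positive class.
* Full-batch training is quadratic in graph size per attention head;
  cohorts beyond a few hundred features per omics need mini-batching or a
  sparse attention implementation, neither of which is provided.
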