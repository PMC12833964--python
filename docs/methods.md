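# Methods

`tonguescreen` implements a dual-branch classifier that screens for
nutritional risk (NRS2002 ≥ 3, the positive class) from a tongue
photograph and its binary tongue mask. This note records the model, the
choices made where the design was genuinely open, and what the synthetic
test bed does and does not establish.

## Problem setting and protocol

Input is an RGB image with a precomputed binary mask delimiting the
tongue; segmentation itself is out of scope. Data are split once into 85%
training and 15% test, stratified by class; a stratified 5-fold plan on
the training part supports cross-validated reporting. All
parameter-fitting steps — normalisation ranges, resampling, feature
selection, classifiers, and the fusion model — see training rows only;
the pipeline records which original rows each component was fitted on,
and a hygiene test asserts the test rows appear in none of them.

## Branch A: hand-crafted features

Each image is mapped to nine channels: R, G, B; full-range BT.601 Y, Cr,
Cb (chroma offset +128); and CIE L\*a\*b\* under D65 from sRGB. Seven
first-order statistics (mean, population SD, skewness, excess kurtosis,
median, min, max) are taken over masked pixels per channel (63 features).
Texture comes from gray-level co-occurrence matrices of the Y channel,
quantised to 32 levels, at distance 1 and angles 0°/45°/90°/135°; a pixel
pair counts only if both ends are inside the mask, and counts are
symmetrised and normalised. Eleven descriptors per angle (contrast,
dissimilarity, homogeneity, ASM, energy, correlation, entropy, maximum
probability, cluster shade, cluster prominence, sum average) give 44
features, 107 in total. Degenerate conventions are pinned so constant
regions are well defined: skewness/kurtosis are 0 at zero variance and
GLCM correlation is 1 at zero marginal variance.

Features are min–max normalised per feature with parameters fitted on
training data; test-time values outside the fitted range are clipped to
[0, 1] (the normalisation's stated codomain), and constant features map
to 0.

### Feature selection (SelectNet)

SelectNet is a stepwise attention network over the normalised feature
vector. Each of T = 3 steps contains:

* a 1-D residual unit `ReLU(Conv(ReLU(Conv(x)))) + x` (kernel 3, padding
  1, one channel) applied to a carrier vector `x_step` (initialised to
  the input);
* a choice block: a linear F→2F map of the original input, ReLU, split
  into halves; the first half gives stage-1 selection logits S1, the
  second an auxiliary transform; the residual unit's output gives stage-2
  logits S2; the selection vector is `M = softmax(S1) ⊙ softmax(S2)`
  (softmaxes over features) and the gated input is `weighted = M ⊙ x`;
* an attention block: the gated input and the carrier form two tokens;
  linear maps produce d = 32-dimensional queries/keys and F-dimensional
  values, scaled dot-product attention mixes them, and batch-normalised
  residual sums produce the decision output
  `x_decision = BN(x + v_decision)` and the next carrier
  `x_step' = BN(x_step + Linear(v_step))`. `v_step` is taken as the
  attention output at the carrier token, so each step's selection
  influences what later steps see; the published equations leave this
  term undefined.

A linear + softmax head reads the final decision output. Feature
importance is the per-feature sum of M over steps, averaged over samples
and normalised to 1; top-k selection keeps the k highest-importance
features (ties to the lower index), k = 30 by default in the pipeline.

Two initialisation choices matter and were made deliberately. First, the
gate-producing layers (the choice linear and the residual-unit
convolutions) start with zero weights and a small positive bias (0.01):
constant logits make both selection softmaxes exactly uniform at
initialisation, so any later concentration is learned signal rather than
init noise, while the positive bias keeps the ReLUs off their
zero-gradient point. Second, the attention value and carrier projections
start at zero (zero-init residual-branch practice), so early gradients
must flow through the selection gates rather than around them. Without
these, the importance ranking reflects initialisation noise: batch
normalisation after the gate makes a uniform gate equally able to
classify, so nothing forces concentration.

Training minimises cross-entropy against (possibly label-smoothed)
targets with Adam, lr 1e-2, batch 64, 80 epochs by default, all seeded.

### Stacking classifier

Four base learners — RBF-kernel SVM (Platt-calibrated probabilities),
random forest (200 trees), 5-NN, and gradient-boosted trees (200 rounds,
depth 4) — produce out-of-fold probabilities via an internal stratified
5-fold split; a logistic meta-learner (L2, C = 1) is fitted on the n×4
out-of-fold matrix, and the bases are refitted on all training rows for
inference. Out-of-fold construction is required so the meta-learner never
scores a base on its own training rows; the fold bookkeeping is stored
and audited in tests. Base hyperparameters are library-typical defaults
recorded in code; no per-dataset tuning is performed by default.

## Class imbalance: CLES

Order of operations: boundary undersampling → interpolation oversampling
→ label smoothing, so synthetic points are never generated from regions
the boundary rule has just cleaned. A majority sample is dropped iff
strictly more than m/2 of its m = 5 nearest neighbours are minority.
Synthetic minority points are `x_i + λ(x_neighbor − x_i)` with λ ~
Uniform(0, 1) (the λ law is unstated in the source method; Uniform is the
SMOTE convention) and the neighbour drawn from the k = 5 nearest minority
points. Oversampling continues until minority:majority = 1 (±1 sample).
Labels become `(1 − ε)·onehot + ε/K` with ε = 0.1. Every output row
records the original row it derives from (synthetic rows point to their
interpolation base), which lets the image branch resample at the image
index level — interpolated images are never fabricated.

## Branch B: shuttle-attention residual CNN

The backbone is a residual CNN; a shuttle block sits inside every
residual unit after the last convolution, before the skip addition. The
block splits channels into g = 4 contiguous groups, halves each group,
applies channel attention (global average pool → one linear layer →
sigmoid) to one half and spatial attention (group normalisation → 1×1
convolution → sigmoid) to the other, concatenates everything and applies
the channel-shuffle permutation `i → (i mod g)(C/g) + ⌊i/g⌋`. Attention
parameters are shared across groups (lightweight design). The printed
fusion equation applies channel attention to both halves; the surrounding
text describes one channel and one spatial half, which is the default
here, with the literal double-channel reading available behind
`double_channel_attention=True`.

Two profiles exist: `resnet50` (bottleneck 3-4-6-3, 224 px inputs, batch
32, lr 1e-4 with cosine annealing — the published full-scale settings)
and `resnet-mini` (three basic-block stages of 16/32/64 channels, 64 px
inputs) for desk-scale work. resnet-mini trains with lr 1e-3 because at
its tiny step count 1e-4 cannot move the loss. Backgrounds are zeroed
through the mask before resizing; pixels are scaled to [0, 1]. Training
uses Adam, cosine-annealed learning rate, and (soft) cross-entropy. No
pretrained weights are used anywhere.

The networks run on a small numpy reverse-mode autodiff engine included
in the package (`tonguescreen._nn`); its analytic gradients are verified
against central finite differences in the test suite.

## Fusion and metrics

The two branch probabilities are fused by logistic regression (intercept,
L2, C = 1) on the 2-feature matrix [score_a, score_b]. Because fusion
must be fitted on scores from data neither branch saw, the pipeline
carves an inner fusion holdout (15% of the training set, stratified);
branches train on the rest, are scored on the holdout to fit the fusion,
and the untouched test set is scored exactly once at the end.

AUC is the Mann–Whitney rank statistic with ties counted 0.5, identical
to the trapezoidal area under the empirical ROC curve (both are computed
and cross-checked). Accuracy, precision and recall use a 0.5 threshold
(none is stated in the source method); precision is 0 when nothing is
predicted positive. The sample-size utility is the classic proportion
estimate `⌈z² p(1−p)/d²⌉`; a "10% confidence-interval width" is read as
half-width d = 0.05, the only reading consistent with the canonical 385
at p = 0.5 and 95% confidence.

## Synthetic test bed

No public dataset exists for this task, so the package ships generators.
Tongue images are axis-aligned ellipses with seed-jittered radii on a
dark background; the at-risk class receives a mean red-channel shift
(`color_effect`, default 30 intensity units) and band-limited coating
noise (Gaussian noise smoothed at σ = 2 px, scaled by `texture_effect`,
default 25); both classes get per-pixel Gaussian noise (SD 8). Default
canvas is 128×128 (the full-scale 1000×1333 remains a config option).
Tabular fixtures are standard-normal matrices whose planted informative
columns are mean-shifted by `delta` in class 1, with ground-truth indices
returned for recovery scoring.

These effects are stipulations, not physiological claims: the generator
emulates a class-conditional color and texture difference, not real
tongue appearance, illumination casts, or acquisition variance. Passing
tests therefore demonstrate that the machinery detects the structure it
is pointed at — recovery of planted features, benefit of resampling,
separation of color-shifted classes, and leak-free protocol — not
clinical performance. The published clinical metrics were computed on a
private 672-image cohort and are not reproducible here.

## Problem sizes used in the shipped checks

Recovery checks run at desk scale on one CPU: SelectNet recovery uses
n = 500, 50 features, 5 informative at delta = 2, 10 seeds; the CLES
comparison uses 600 samples at 9:1 imbalance, 10 paired seeds; the CNN
check trains resnet-mini for 5 epochs on 200 images at 64×64 with
color_effect 40; the fusion property uses ten 48-image pipeline runs with
a 1-epoch CNN; the full pipeline example uses 300 images. These sizes
were chosen so the whole suite runs in minutes while keeping every
statistic comfortably away from its decision boundary.

## Known limitations

* The numpy engine is single-threaded float64; the resnet50 profile is
  provided for structural completeness and full-size runs are slow —
  resnet-mini is the supported desk-scale path.
* The importance statistic is the softmax-gate mean; it identifies
  rankings, not calibrated effect sizes, and softmax coupling means
  correlated informative features can share (and dilute) gate mass.
* With strongly separable synthetic defaults, test metrics saturate at
  1.0; the fixtures are a correctness surface, not a benchmark.
* Fusion assumes the two branch scores are probabilities on a common
  sample set aligned by index; no calibration is applied.
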