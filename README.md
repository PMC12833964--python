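# tonguescreen

Screening hospital patients for nutritional risk with NRS2002 takes
minutes of nurse-led interviewing per round; tongue appearance — color,
coating, texture — carries enough signal to predict the binary screening
outcome (NRS2002 ≥ 3, "at risk") from a photograph. `tonguescreen` is a
library and CLI implementing a dual-branch classifier for that task, for
researchers who have tongue photographs with tongue masks and binary risk
labels (or who want to exercise the method end-to-end on the built-in
synthetic fixtures — no dataset is bundled or downloaded).

The two branches and their fusion:

* **Branch A (interpretable features).** 107 hand-crafted features per
  image: 9 color channels (RGB, full-range BT.601 YCrCb, CIE L\*a\*b\*)
  × 7 masked first-order statistics, plus gray-level co-occurrence
  texture (32 levels, distance 1, angles 0°/45°/90°/135°, 11
  Haralick-style descriptors each). Features are min–max normalised
  (k′ = (k − k_min)/(k_max − k_min), fitted on training data), filtered
  by **SelectNet** — a stepwise attention network whose per-feature
  selection vectors M = softmax(S1) ⊙ softmax(S2) yield a normalised
  importance ranking — and classified by a stacking ensemble (RBF-SVM,
  random forest, k-NN, XGBoost; logistic meta-learner on out-of-fold
  probabilities).
* **Branch B (deep features).** A residual CNN whose residual units embed
  a *shuttle attention* block: channels are split into g groups, each
  halved into a channel-attention part σ(Linear(GAP(X))) ⊙ X and a
  spatial-attention part σ(Conv₁ₓ₁(GN(X))) ⊙ X, then concatenated and
  channel-shuffled for cross-group flow. Backbones: `resnet50` and a
  desk-scale `resnet-mini`. The networks run on a small numpy autodiff
  engine bundled with the package.
* **Imbalance (CLES).** Boundary undersampling of ambiguous majority
  samples, interpolation oversampling x_new = x_i + λ(x_neighbor − x_i)
  of the minority class, and label smoothing (1 − ε)·onehot + ε/K.
* **Fusion.** The two branch probabilities are two features of a logistic
  regression, fitted on an inner holdout so neither branch scores its own
  training data; the 15% test split is scored exactly once.

Metrics are AUC (Mann–Whitney rank statistic, ties 0.5), accuracy,
precision, recall, ROC points and confusion counts; a sample-size utility
⌈z²p(1−p)/d²⌉ covers the design-stage prevalence estimate.

## Worked example

Generate a synthetic cohort, run the full pipeline, and read the report:

```python
from tonguescreen.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(n_images=300, seed=1))
print({k: round(v, 3) for k, v in report["test"]["fused"].items()
       if k != "confusion"})
print(report["test"]["fused"]["confusion"])
```

prints (strongly separable fixture defaults: +30 red-channel shift and
+25 coating-texture amplitude for the at-risk class):

```
{'auc': 1.0, 'acc': 1.0, 'precision': 1.0, 'recall': 1.0}
{'tp': 23, 'fp': 0, 'tn': 22, 'fn': 0}
```

i.e. on the 45-image untouched test split, both branches and their fusion
separate the two synthetic classes perfectly — the fixtures are a
correctness surface, not a benchmark (see `docs/methods.md`). The report
also carries per-branch metrics, the selected feature names, the two
fusion coefficients, 5-fold cross-validation metrics for branch A, and an
audit trail of which rows every component was fitted on.

The same flow is available from the shell:

```sh
tonguescreen simulate --n 300 --seed 1 --out data/synth
tonguescreen extract --data data/synth --out features.csv
tonguescreen evaluate --seed 1 --out report.json
tonguescreen sample-size --prevalence 0.5 --conf-level 0.95 --half-width 0.05
# -> 385
```

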