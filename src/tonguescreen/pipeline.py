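"""End-to-end orchestration of the dual-branch screening pipeline.

Flow: images + masks -> hand-crafted features -> min-max normalisation
(fitted on training data only) -> CLES resampling (training data only) ->
SelectNet feature selection + stacking ensemble (branch A) -> shuttle-
attention CNN (branch B) -> logistic fusion fitted on an inner held-out
subset of the training data -> final metrics on the untouched 15% test
set.  Every random choice derives from one integer seed and the run is
bit-reproducible.

The fusion model must see branch scores from data neither branch was
trained on; a ``fusion_fraction`` slice of the training set is held out
for that purpose, and the 15% test split is used exactly once, for final
scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import manual_features as mf
from .cles import CLESConfig, apply_cles
from .ensemble_fusion import fit_stacking, predict_stacking, fuse_branches, predict_fused
from .evaluation import compute_metrics, stratified_split
from .fixtures import SyntheticImageParams, make_image_dataset, load_image_dataset
from .selectnet import SelectNetConfig, train_selectnet, select_top_k
from .shuttle_attention import ShuttleConfig, train_cnn_branch, predict_proba

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    # data source: a dataset directory (images/, masks/, labels.csv) or
    # synthetic fixture parameters
    dataset_dir: str | None = None
    n_images: int = 300
    image: dict = field(default_factory=dict)      # SyntheticImageParams overrides
    # protocol
    seed: int = 0
    test_fraction: float = 0.15
    n_folds: int = 5
    run_cv: bool = True
    fusion_fraction: float = 0.15
    threshold: float = 0.5
    # component settings
    cles: dict = field(default_factory=dict)       # CLESConfig overrides
    selectnet: dict = field(default_factory=dict)  # SelectNetConfig overrides
    top_k: int = 30
    cnn: dict = field(default_factory=dict)        # ShuttleConfig overrides


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**raw)


def _branch_a_fit(X_train, y_train, cfg: PipelineConfig, seed: int):
    """Normalise -> CLES -> SelectNet selection -> stacking, on training
    rows only.  Returns the fitted transforms and models."""
    norm = mf.fit_minmax(X_train)
    Xn = mf.apply_minmax(X_train, norm)
    cles_cfg = CLESConfig(**{"seed": seed, **cfg.cles})
    res = apply_cles(np.asarray(Xn, float), y_train, cles_cfg)
    sn_cfg = SelectNetConfig(
        **{"feature_dim": res.X.shape[1], "seed": seed, **cfg.selectnet})
    sn_model = train_selectnet(res.X, res.y_soft, sn_cfg)
    _, selected = select_top_k(sn_model, res.X, cfg.top_k)
    stack_model = fit_stacking(res.X[:, selected], res.y, seed=seed)
    return norm, res, sn_model, selected, stack_model


def _branch_a_predict(stack_model, norm, selected, X):
    Xn = np.asarray(mf.apply_minmax(X, norm), float)
    return predict_stacking(stack_model, Xn[:, selected])


def run_pipeline(cfg: PipelineConfig, out_path: str | Path | None = None) -> dict:
    """Run the full dual-branch pipeline and return a JSON-able report."""
    # -- data ----------------------------------------------------------------
    if cfg.dataset_dir is not None:
        ds = load_image_dataset(cfg.dataset_dir)
    else:
        params = SyntheticImageParams(**{"seed": cfg.seed, **cfg.image})
        ds = make_image_dataset(cfg.n_images, params)
    y = ds.labels
    n = len(ds)

    plan = stratified_split(y, cfg.test_fraction, cfg.n_folds, cfg.seed)
    train_idx, test_idx = plan.train_idx, plan.test_idx

    # feature extraction is a pure per-image function (nothing fitted)
    features = mf.extract_feature_table(ds.images, ds.masks)
    X = features.to_numpy()

    # inner fusion holdout carved from the training set
    rng = np.random.default_rng(cfg.seed + 17)
    fuse_plan = stratified_split(y[train_idx], cfg.fusion_fraction,
                                 n_folds=2, seed=int(rng.integers(2**31)))
    fit_idx = train_idx[fuse_plan.train_idx]       # branch-training rows
    hold_idx = train_idx[fuse_plan.test_idx]       # fusion-fitting rows

    audit = {
        "train_indices": train_idx.tolist(),
        "test_indices": test_idx.tolist(),
        "fusion_holdout_indices": hold_idx.tolist(),
        "fit_components": {},
    }

    # -- branch A ------------------------------------------------------------
    norm, cles_res, sn_model, selected, stack_model = _branch_a_fit(
        X[fit_idx], y[fit_idx], cfg, cfg.seed)
    audit["fit_components"]["minmax"] = fit_idx.tolist()
    audit["fit_components"]["cles"] = fit_idx.tolist()
    audit["fit_components"]["selectnet"] = fit_idx.tolist()
    audit["fit_components"]["stacking"] = fit_idx.tolist()
    score_a_hold = _branch_a_predict(stack_model, norm, selected, X[hold_idx])
    score_a_test = _branch_a_predict(stack_model, norm, selected, X[test_idx])

    # -- branch B ------------------------------------------------------------
    # image-level resampling: reuse the CLES kept/duplicated row indices
    # (synthetic rows fall back to their interpolation base image)
    img_rows = fit_idx[cles_res.source_index]
    cnn_cfg = ShuttleConfig(**{"seed": cfg.seed, **cfg.cnn})
    cnn_images = [ds.images[i] for i in img_rows]
    cnn_masks = [ds.masks[i] for i in img_rows]
    cnn_model, score_b_hold = train_cnn_branch(
        cnn_images, cnn_masks, cles_res.y_soft, cnn_cfg,
        eval_images=[ds.images[i] for i in hold_idx],
        eval_masks=[ds.masks[i] for i in hold_idx])
    audit["fit_components"]["cnn"] = sorted(set(img_rows.tolist()))
    score_b_test = predict_proba(cnn_model, [ds.images[i] for i in test_idx],
                                 [ds.masks[i] for i in test_idx])

    # -- fusion --------------------------------------------------------------
    fusion, _ = fuse_branches(score_a_hold, score_b_hold, y[hold_idx],
                              seed=cfg.seed)
    audit["fit_components"]["fusion"] = hold_idx.tolist()
    fused_test = predict_fused(fusion, score_a_test, score_b_test)

    report = {
        "n": n,
        "seed": cfg.seed,
        "selected_features": [features.columns[i] for i in selected],
        "fusion": {"coef": fusion.coefficients.tolist(),
                   "intercept": fusion.intercept},
        "test": {
            "branch_a": compute_metrics(score_a_test, y[test_idx],
                                        cfg.threshold).to_dict(),
            "branch_b": compute_metrics(score_b_test, y[test_idx],
                                        cfg.threshold).to_dict(),
            "fused": compute_metrics(fused_test, y[test_idx],
                                     cfg.threshold).to_dict(),
        },
        "scores": {
            "test_branch_a": score_a_test.tolist(),
            "test_branch_b": score_b_test.tolist(),
            "test_fused": fused_test.tolist(),
            "test_labels": y[test_idx].tolist(),
        },
        "audit": audit,
    }

    # -- 5-fold CV of branch A on the training set ---------------------------
    if cfg.run_cv:
        fold_metrics = []
        for f in range(plan.n_folds):
            tr = train_idx[plan.folds != f]
            va = train_idx[plan.folds == f]
            norm_f = mf.fit_minmax(X[tr])
            res_f = apply_cles(np.asarray(mf.apply_minmax(X[tr], norm_f), float),
                               y[tr], CLESConfig(**{"seed": cfg.seed + f,
                                                    **cfg.cles}))
            stack_f = fit_stacking(res_f.X[:, selected], res_f.y,
                                   seed=cfg.seed + f)
            sc = predict_stacking(
                stack_f, np.asarray(mf.apply_minmax(X[va], norm_f),
                                    float)[:, selected])
            fold_metrics.append(compute_metrics(sc, y[va], cfg.threshold))
        report["cv_branch_a"] = {
            "auc_mean": float(np.mean([m.auc for m in fold_metrics])),
            "auc_sd": float(np.std([m.auc for m in fold_metrics])),
            "acc_mean": float(np.mean([m.acc for m in fold_metrics])),
            "folds": [m.to_dict() for m in fold_metrics],
        }

    if out_path is not None:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        Path(out_path).write_text(json.dumps(report, indent=2))
    return report
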