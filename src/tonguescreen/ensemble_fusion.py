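"""Branch-A stacking classifier and the final two-branch logistic fusion.

The stacking model trains four base learners — an RBF-kernel support
vector machine, a random forest, k-nearest neighbours and gradient-boosted
trees — and a logistic-regression meta-learner on their *out-of-fold*
probability predictions (internal stratified 5-fold split), so the
meta-learner never sees a base prediction made on that base's own training
fold.  The two branch scores are fused by a 2-feature logistic regression
with intercept and L2 penalty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = [
    "StackingModel", "FusionModel",
    "fit_stacking", "predict_stacking", "fuse_branches", "predict_fused",
]

BASE_LEARNER_NAMES = ("svm", "rf", "knn", "xgb")


def _base_learners(seed: int) -> dict:
    return {
        # RBF-kernel SVM with Platt-calibrated probabilities
        "svm": CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed),
                                      method="sigmoid", ensemble=False),
        "rf": RandomForestClassifier(n_estimators=200, random_state=seed),
        "knn": KNeighborsClassifier(n_neighbors=5),
        "xgb": XGBClassifier(
            n_estimators=200, max_depth=4, learning_rate=0.1,
            eval_metric="logloss", random_state=seed, n_jobs=1,
        ),
    }


@dataclass
class StackingModel:
    base: dict
    meta: LogisticRegression
    oof_matrix: np.ndarray            # n x 4 out-of-fold meta-features
    fold_assignments: np.ndarray      # audit trail of the internal split
    seed: int


@dataclass
class FusionModel:
    model: LogisticRegression

    @property
    def coefficients(self) -> np.ndarray:
        return self.model.coef_.ravel()

    @property
    def intercept(self) -> float:
        return float(self.model.intercept_[0])

    def to_json(self, path: str | Path):
        Path(path).write_text(json.dumps({
            "coef": self.coefficients.tolist(), "intercept": self.intercept}))


def fit_stacking(X: np.ndarray, y: np.ndarray, seed: int = 0,
                 n_folds: int = 5) -> StackingModel:
    """Fit the four base learners + logistic meta-learner with out-of-fold
    meta-features; bases are refit on the full data for inference."""
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if len(y) < 20:
        raise ValueError("need at least 20 samples for stable stacking")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(cv.split(X, y)):
        folds[test_idx] = f
    learners = _base_learners(seed)
    oof = np.column_stack([
        cross_val_predict(learners[name], X, y, cv=cv,
                          method="predict_proba")[:, 1]
        for name in BASE_LEARNER_NAMES
    ])
    meta = LogisticRegression(C=1.0, max_iter=1000, random_state=seed)
    meta.fit(oof, y)
    for name in BASE_LEARNER_NAMES:
        learners[name].fit(X, y)
    return StackingModel(learners, meta, oof, folds, seed)


def predict_stacking(model: StackingModel, X: np.ndarray) -> np.ndarray:
    """Class-1 probability of the stacked ensemble."""
    X = np.asarray(X, float)
    n_feat = model.base["rf"].n_features_in_
    if X.shape[1] != n_feat:
        raise ValueError(f"expected {n_feat} features, got {X.shape[1]}")
    meta_X = np.column_stack([
        model.base[name].predict_proba(X)[:, 1] for name in BASE_LEARNER_NAMES
    ])
    return model.meta.predict_proba(meta_X)[:, 1]


def fuse_branches(score_a: np.ndarray, score_b: np.ndarray, y: np.ndarray,
                  seed: int = 0) -> tuple[FusionModel, np.ndarray]:
    """Logistic fusion of the two branch probabilities.

    Scores must come from data not used to fit either branch (held-out or
    cross-validated).  Returns the fitted 2-coefficient model and the
    fused probabilities on the same samples.
    """
    score_a = np.asarray(score_a, float)
    score_b = np.asarray(score_b, float)
    y = np.asarray(y, int)
    if not (len(score_a) == len(score_b) == len(y)):
        raise ValueError("branch scores and labels are misaligned")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    Z = np.column_stack([score_a, score_b])
    lr = LogisticRegression(C=1.0, max_iter=1000, random_state=seed)
    lr.fit(Z, y)
    fused = FusionModel(lr)
    return fused, lr.predict_proba(Z)[:, 1]


def predict_fused(fused: FusionModel, score_a: np.ndarray,
                  score_b: np.ndarray) -> np.ndarray:
    Z = np.column_stack([np.asarray(score_a, float), np.asarray(score_b, float)])
    return fused.model.predict_proba(Z)[:, 1]
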