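"""CLES — a comprehensive class-imbalance strategy for binary tabular data.

Three components applied in order:

1. **Boundary undersampling** of the majority class: a majority sample is
   dropped iff strictly more than half of its m nearest neighbours belong
   to the minority class, i.e. it sits in the ambiguous overlap region.
2. **Smooth oversampling** of the minority class: synthetic points are
   drawn by linear interpolation ``x_new = x_i + lam * (x_neighbor - x_i)``
   between a minority point and one of its k nearest minority neighbours,
   with ``lam ~ Uniform(0, 1)``.
3. **Label smoothing**: hard labels are replaced by
   ``(1 - eps) * onehot + eps / K`` soft targets.

Undersampling runs first so synthetic minority points are not interpolated
toward regions the boundary rule has just cleaned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "CLESConfig", "CLESResult",
    "smooth_oversample", "boundary_undersample", "smooth_labels", "apply_cles",
]


@dataclass(frozen=True)
class CLESConfig:
    k_neighbors: int = 5
    m_neighbors: int = 5
    target_ratio: float = 1.0       # desired minority : majority count ratio
    epsilon: float = 0.1            # label-smoothing strength
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.k_neighbors < 1 or self.m_neighbors < 1:
            raise ValueError("neighbour counts must be >= 1")
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError("epsilon must lie in [0, 1)")
        if self.target_ratio <= 0:
            raise ValueError("target_ratio must be positive")


@dataclass
class CLESResult:
    """Resampled design matrix with hard and smoothed labels.

    ``source_index`` maps each output row to the original row it came from
    (for synthetic rows: the interpolation base x_i).  This lets paired
    data — e.g. the images behind a feature table — be resampled at the
    index level without generating interpolated images.
    """

    X: np.ndarray
    y: np.ndarray
    y_soft: np.ndarray
    source_index: np.ndarray
    is_synthetic: np.ndarray


def smooth_oversample(X_minority: np.ndarray, k: int, n_new: int,
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Generate n_new synthetic minority samples by k-NN interpolation.

    Returns (samples, base_indices) where base_indices[i] is the row of
    X_minority used as the interpolation base x_i.
    """
    X = np.asarray(X_minority, float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 minority samples to interpolate")
    k = min(k, n - 1)
    rng = np.random.default_rng(seed)
    if n_new == 0:
        return np.empty((0, X.shape[1])), np.empty(0, dtype=int)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    neigh = nn.kneighbors(X, return_distance=False)[:, 1:]  # drop self
    base = rng.integers(0, n, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    lam = rng.uniform(0.0, 1.0, size=n_new)
    xi = X[base]
    xn = X[neigh[base, pick]]
    return xi + lam[:, None] * (xn - xi), base


def boundary_undersample(X: np.ndarray, y: np.ndarray, m: int = 5) -> np.ndarray:
    """Indices kept after removing ambiguous majority samples.

    A majority sample is removed iff strictly more than m/2 of its m
    nearest neighbours (self excluded) are minority.  Minority samples are
    always kept.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    minority = classes[np.argmin(counts)]
    m = min(m, len(y) - 1)
    nn = NearestNeighbors(n_neighbors=m + 1).fit(X)
    neigh = nn.kneighbors(X, return_distance=False)[:, 1:]
    minority_frac_count = (y[neigh] == minority).sum(axis=1)
    drop = (y != minority) & (minority_frac_count > m / 2.0)
    return np.flatnonzero(~drop)


def smooth_labels(y: np.ndarray, epsilon: float, n_classes: int = 2) -> np.ndarray:
    """Soft targets (1 - eps) * onehot + eps / K; rows sum to 1."""
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must lie in [0, 1)")
    y = np.asarray(y, int)
    if y.min() < 0 or y.max() >= n_classes:
        raise ValueError("labels out of range")
    onehot = np.eye(n_classes)[y]
    return (1.0 - epsilon) * onehot + epsilon / n_classes


def apply_cles(X: np.ndarray, y: np.ndarray, config: CLESConfig = CLESConfig()) -> CLESResult:
    """Run the full strategy: undersample -> oversample -> smooth -> shuffle.

    After processing, minority:majority counts equal ``target_ratio`` up to
    one sample.  Output order is a seeded permutation.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("apply_cles expects binary labels with both classes present")
    minority = int(classes[np.argmin(counts)])

    kept = boundary_undersample(X, y, config.m_neighbors)
    Xk, yk = X[kept], y[kept]

    n_min = int((yk == minority).sum())
    n_maj = int((yk != minority).sum())
    n_target = int(round(config.target_ratio * n_maj))
    n_new = max(0, n_target - n_min)

    min_rows = np.flatnonzero(yk == minority)
    if n_new > 0:
        synth, base = smooth_oversample(Xk[min_rows], config.k_neighbors,
                                        n_new, seed=config.seed)
        X_all = np.vstack([Xk, synth])
        y_all = np.concatenate([yk, np.full(n_new, minority, dtype=int)])
        src = np.concatenate([kept, kept[min_rows[base]]])
        syn_flag = np.concatenate([np.zeros(len(kept), bool), np.ones(n_new, bool)])
    else:
        X_all, y_all = Xk, yk
        src = kept.copy()
        syn_flag = np.zeros(len(kept), bool)

    y_soft = smooth_labels(y_all, config.epsilon, config.n_classes)
    order = np.random.default_rng(config.seed + 1).permutation(len(y_all))
    return CLESResult(X_all[order], y_all[order], y_soft[order],
                      src[order], syn_flag[order])
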