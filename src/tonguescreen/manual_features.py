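"""Hand-crafted tongue-image features: multi-color-space first-order
statistics plus gray-level co-occurrence (GLCM) texture descriptors.

The default inventory is 107-dimensional:

* 9 channels (R, G, B; Y, Cr, Cb; L*, a*, b*) × 7 first-order statistics
  (mean, std, skewness, kurtosis, median, min, max) over the masked tongue
  region = 63 features;
* GLCM of the luma channel (quantised to 32 gray levels) at distance 1 for
  angles 0°, 45°, 90°, 135°, each summarised by 11 Haralick-style
  descriptors = 44 features.

Conventions pinned for reproducibility: YCrCb is full-range ITU-R BT.601
with a +128 chroma offset; L*a*b* is CIE Lab under D65 from sRGB; moments
use the population (n) denominator; skewness/kurtosis of a constant region
are defined as 0 and GLCM correlation as 1 when a marginal variance is 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.color import rgb2lab

__all__ = [
    "TongueImage", "MinMaxParams",
    "convert_color_spaces", "masked_first_order_stats",
    "compute_glcm", "glcm_descriptors", "extract_features",
    "extract_feature_table", "feature_names",
    "fit_minmax", "apply_minmax",
]

CHANNEL_NAMES = ("R", "G", "B", "Y", "Cr", "Cb", "L", "a", "b")
STAT_NAMES = ("mean", "std", "skewness", "kurtosis", "median", "min", "max")
GLCM_ANGLES = (0, 45, 90, 135)
DESCRIPTOR_NAMES = (
    "contrast", "dissimilarity", "homogeneity", "asm", "energy", "correlation",
    "entropy", "max_probability", "cluster_shade", "cluster_prominence",
    "sum_average",
)
DEFAULT_GLCM_LEVELS = 32

# Pixel-pair offsets (drow, dcol) per angle at unit distance, standard
# Haralick orientation (0 deg = horizontal neighbour to the right).
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class TongueImage:
    """An RGB tongue photograph with its binary tongue mask."""

    rgb: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.rgb = np.asarray(self.rgb)
        self.mask = (np.asarray(self.mask) > 0).astype(np.uint8)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be an H x W x 3 raster")
        if self.mask.shape != self.rgb.shape[:2]:
            raise ValueError("mask dimensions must match the image")
        if self.mask.sum() == 0:
            raise ValueError("mask is empty")


@dataclass
class MinMaxParams:
    k_min: np.ndarray
    k_max: np.ndarray

    def to_json(self, path: str | Path):
        Path(path).write_text(json.dumps(
            {"k_min": self.k_min.tolist(), "k_max": self.k_max.tolist()}))

    @classmethod
    def from_json(cls, path: str | Path) -> "MinMaxParams":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["k_min"], float), np.asarray(d["k_max"], float))


def convert_color_spaces(image: TongueImage) -> dict[str, np.ndarray]:
    """Map an RGB image to the 9 channels R,G,B / Y,Cr,Cb / L*,a*,b*."""
    rgb = image.rgb.astype(float)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    # full-range BT.601 luma/chroma with +128 offset
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cr = (r - y) * 0.713 + 128.0
    cb = (b - y) * 0.564 + 128.0
    lab = rgb2lab(image.rgb)  # sRGB -> CIE Lab, D65 illuminant
    return {
        "R": r, "G": g, "B": b,
        "Y": y, "Cr": cr, "Cb": cb,
        "L": lab[..., 0], "a": lab[..., 1], "b": lab[..., 2],
    }


def masked_first_order_stats(channel: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Seven first-order statistics over masked pixels.

    Returns (mean, std, skewness, kurtosis, median, min, max).  Population
    moments; Fisher (excess) kurtosis; skewness and kurtosis are 0 by
    convention when the masked region is constant.
    """
    vals = np.asarray(channel, float)[np.asarray(mask) > 0]
    if vals.size == 0:
        raise ValueError("mask is empty")
    mean = vals.mean()
    std = vals.std()  # population denominator
    if std == 0:
        skew = kurt = 0.0
    else:
        z = (vals - mean) / std
        skew = float((z**3).mean())
        kurt = float((z**4).mean() - 3.0)
    return np.array([mean, std, skew, kurt, np.median(vals), vals.min(), vals.max()])


def quantize_gray(gray: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly quantise intensities in [0, 255] into `levels` bins."""
    q = np.floor(np.clip(gray, 0, 255) / 256.0 * levels).astype(int)
    return np.clip(q, 0, levels - 1)


def compute_glcm(gray: np.ndarray, mask: np.ndarray, distance: int = 1,
                 angle: int = 0, levels: int = DEFAULT_GLCM_LEVELS) -> np.ndarray:
    """Masked, symmetrised, normalised gray-level co-occurrence matrix.

    A pixel pair contributes only when both endpoints lie inside the mask.
    The returned `levels` x `levels` matrix is symmetric and sums to 1.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if angle not in _ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_ANGLE_OFFSETS)}")
    q = quantize_gray(np.asarray(gray, float), levels)
    m = np.asarray(mask) > 0
    dr, dc = _ANGLE_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    h, w = q.shape

    # slices of the source and offset pixel grids
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    src = q[r0:r1, c0:c1]
    dst = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = m[r0:r1, c0:c1] & m[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    if not valid.any():
        raise ValueError("no valid pixel pairs inside the mask at this offset")

    idx = src[valid] * levels + dst[valid]
    counts = np.bincount(idx, minlength=levels * levels).reshape(levels, levels)
    counts = counts + counts.T  # symmetrise (count both pair orders)
    return counts / counts.sum()


def glcm_descriptors(P: np.ndarray) -> dict[str, float]:
    """Eleven Haralick-style texture descriptors of a normalised GLCM."""
    P = np.asarray(P, float)
    levels = P.shape[0]
    i, j = np.mgrid[0:levels, 0:levels]
    pi = P.sum(axis=1)  # marginal (symmetric, so both marginals equal)
    mu = (np.arange(levels) * pi).sum()
    var = (((np.arange(levels) - mu) ** 2) * pi).sum()

    contrast = ((i - j) ** 2 * P).sum()
    dissimilarity = (np.abs(i - j) * P).sum()
    homogeneity = (P / (1.0 + (i - j) ** 2)).sum()
    asm = (P**2).sum()
    energy = np.sqrt(asm)
    if var > 0:
        correlation = (((i - mu) * (j - mu) * P).sum()) / var
    else:
        correlation = 1.0  # degenerate single-level distribution
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(P > 0, np.log(P), 0.0)
    entropy = -(P * logp).sum()
    shade = (((i - mu) + (j - mu)) ** 3 * P).sum()
    prominence = (((i - mu) + (j - mu)) ** 4 * P).sum()
    sum_average = ((i + j) * P).sum()
    return {
        "contrast": float(contrast),
        "dissimilarity": float(dissimilarity),
        "homogeneity": float(homogeneity),
        "asm": float(asm),
        "energy": float(energy),
        "correlation": float(correlation),
        "entropy": float(entropy),
        "max_probability": float(P.max()),
        "cluster_shade": float(shade),
        "cluster_prominence": float(prominence),
        "sum_average": float(sum_average),
    }


def feature_names(levels: int = DEFAULT_GLCM_LEVELS) -> list[str]:
    """Stable ordering of the default 107-feature inventory."""
    names = [f"{ch}_{st}" for ch in CHANNEL_NAMES for st in STAT_NAMES]
    names += [f"glcm_d1_a{ang}_{d}" for ang in GLCM_ANGLES for d in DESCRIPTOR_NAMES]
    return names


def extract_features(image: TongueImage,
                     glcm_levels: int = DEFAULT_GLCM_LEVELS) -> pd.Series:
    """Extract the full hand-crafted feature vector for one image.

    Returns a named pandas Series of length 107 (default config).  Only
    pixels inside the mask contribute, so the vector is invariant to any
    background edit.
    """
    channels = convert_color_spaces(image)
    values: list[float] = []
    for ch in CHANNEL_NAMES:
        values.extend(masked_first_order_stats(channels[ch], image.mask))
    gray = channels["Y"]
    for ang in GLCM_ANGLES:
        P = compute_glcm(gray, image.mask, distance=1, angle=ang, levels=glcm_levels)
        desc = glcm_descriptors(P)
        values.extend(desc[d] for d in DESCRIPTOR_NAMES)
    return pd.Series(values, index=feature_names(glcm_levels), dtype=float)


def extract_feature_table(images, masks, glcm_levels: int = DEFAULT_GLCM_LEVELS) -> pd.DataFrame:
    """Feature matrix (rows = images) for aligned image/mask sequences."""
    rows = [extract_features(TongueImage(img, m), glcm_levels)
            for img, m in zip(images, masks)]
    return pd.DataFrame(rows).reset_index(drop=True)


def fit_minmax(table: np.ndarray | pd.DataFrame) -> MinMaxParams:
    """Per-feature min/max fitted on training data only."""
    arr = np.asarray(table, float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need a non-empty 2-D table")
    return MinMaxParams(arr.min(axis=0), arr.max(axis=0))


def apply_minmax(table: np.ndarray | pd.DataFrame, params: MinMaxParams):
    """k' = (k - k_min) / (k_max - k_min), clipped to [0, 1].

    Constant features map to 0; values outside the fitted range clip to the
    interval boundaries so the codomain is always [0, 1].
    """
    is_frame = isinstance(table, pd.DataFrame)
    arr = np.asarray(table, float)
    if arr.shape[1] != params.k_min.shape[0]:
        raise ValueError("feature dimension does not match fitted parameters")
    span = params.k_max - params.k_min
    safe = np.where(span > 0, span, 1.0)
    out = np.clip((arr - params.k_min) / safe, 0.0, 1.0)
    out[:, span == 0] = 0.0
    if is_frame:
        return pd.DataFrame(out, columns=table.columns, index=table.index)
    return out
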