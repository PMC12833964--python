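"""Synthetic tongue-image and tabular-feature generators.

No public tongue-image dataset accompanies the screening task this package
addresses, so every other module is exercised on synthetic data with
controllable class-conditional structure.  The image generator draws an
ellipse-like "tongue" on a dark background; images of the at-risk class
receive a mean red-channel shift (``color_effect``) and band-limited
coating noise (``texture_effect``).  These effects are stipulations chosen
to give the two classes a detectable color and texture difference — they
are not claims about the physiology of at-risk tongues.

All generators are pure functions of their seeds: calling twice with the
same arguments returns bit-identical arrays.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "SyntheticImageParams", "LabeledImageSet", "LabeledFeatureSet",
    "make_tongue_image", "make_image_dataset", "make_feature_dataset",
    "save_image_dataset", "load_image_dataset",
]

# Per-instance seed scheme: seed_i = base_seed * _SEED_STRIDE + index.
# Large odd stride keeps instance streams disjoint at desk scale.
_SEED_STRIDE = 10007

# Base coloring of the synthetic tongue body (reddish) and the background.
_TONGUE_RGB = np.array([170.0, 95.0, 100.0])
_BACKGROUND = 30.0


@dataclass(frozen=True)
class SyntheticImageParams:
    """Parameters of the synthetic tongue-image generator.

    color_effect and texture_effect act on the positive (at-risk) class
    only; both are in 8-bit intensity units.
    """

    height: int = 128
    width: int = 128
    pos_fraction: float = 0.5
    color_effect: float = 30.0
    texture_effect: float = 25.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.height < 32 or self.width < 32:
            raise ValueError("image dimensions must be at least 32 pixels")
        if not 0.0 <= self.pos_fraction <= 1.0:
            raise ValueError("pos_fraction must lie in [0, 1]")
        if min(self.color_effect, self.texture_effect, self.noise_sd) < 0:
            raise ValueError("effect sizes must be non-negative")


@dataclass
class LabeledImageSet:
    images: list[np.ndarray]
    masks: list[np.ndarray]
    labels: np.ndarray
    params: SyntheticImageParams | None = None

    def __post_init__(self):
        if not (len(self.images) == len(self.masks) == len(self.labels)):
            raise ValueError("images, masks and labels must have equal length")
        self.labels = np.asarray(self.labels, dtype=int)

    def __len__(self):
        return len(self.images)


@dataclass
class LabeledFeatureSet:
    features: np.ndarray
    labels: np.ndarray
    informative_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.informative_idx = np.asarray(self.informative_idx, dtype=int)
        if np.isnan(self.features).any():
            raise ValueError("feature matrix contains missing values")


def make_tongue_image(label: int, params: SyntheticImageParams,
                      instance_seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Render one synthetic tongue image and its binary mask.

    Returns (image, mask): image is uint8 H×W×3, mask is uint8 H×W in {0,1}.
    The tongue is an axis-aligned ellipse with seed-jittered radii so that
    masks vary between instances while remaining single 4-connected
    components.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    h, w = params.height, params.width
    rng = np.random.default_rng(instance_seed)

    # ellipse geometry: centred, radii jittered +-8 %
    ry = 0.36 * h * rng.uniform(0.92, 1.08)
    rx = 0.42 * w * rng.uniform(0.92, 1.08)
    cy, cx = h / 2.0, w / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0).astype(np.uint8)

    img = np.full((h, w, 3), _BACKGROUND, dtype=float)
    body = _TONGUE_RGB.copy()
    if label == 1:
        body[0] += params.color_effect  # red-channel shift for the at-risk class
    img[mask == 1] = body

    if label == 1 and params.texture_effect > 0:
        # band-limited coating texture: smoothed white noise, unit-variance
        raw = rng.normal(0.0, 1.0, (h, w))
        smooth = ndimage.gaussian_filter(raw, sigma=2.0)
        sd = smooth.std()
        if sd > 0:
            smooth = smooth / sd
        img[:, :, 0] += params.texture_effect * smooth * mask
        img[:, :, 1] += params.texture_effect * smooth * mask
        img[:, :, 2] += params.texture_effect * smooth * mask

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, (h, w, 3))

    return np.clip(img, 0, 255).astype(np.uint8), mask


def make_image_dataset(n: int, params: SyntheticImageParams) -> LabeledImageSet:
    """Generate a labelled set of n images with round(n * pos_fraction) positives.

    Labels are assigned by a seeded permutation; instance i is rendered with
    seed ``params.seed * 10007 + i`` so datasets are reproducible and
    extendable.
    """
    if n < 2:
        raise ValueError("need at least 2 images")
    n_pos = int(round(n * params.pos_fraction))
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng = np.random.default_rng(params.seed)
    labels = labels[rng.permutation(n)]

    images, masks = [], []
    for i, lab in enumerate(labels):
        img, mask = make_tongue_image(int(lab), params, params.seed * _SEED_STRIDE + i)
        images.append(img)
        masks.append(mask)
    return LabeledImageSet(images, masks, labels, params)


def make_feature_dataset(n: int, dim: int, n_informative: int, delta: float,
                         pos_fraction: float = 0.5, seed: int = 0) -> LabeledFeatureSet:
    """Gaussian feature matrix with class-shifted informative columns.

    All columns are standard normal; for the ``n_informative`` randomly
    chosen informative columns the class-1 mean is shifted by ``delta``.
    The informative indices are returned so selection methods can be scored
    against ground truth.
    """
    if n_informative > dim:
        raise ValueError("n_informative cannot exceed dim")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n * pos_fraction))
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    labels = labels[rng.permutation(n)]
    X = rng.normal(0.0, 1.0, (n, dim))
    informative = np.sort(rng.choice(dim, size=n_informative, replace=False))
    X[np.ix_(labels == 1, informative)] += delta
    return LabeledFeatureSet(X, labels, informative)


# -- disk round-trip ---------------------------------------------------------

def save_image_dataset(ds: LabeledImageSet, outdir: str | Path) -> Path:
    """Write images/masks as PNG, labels as CSV, parameters as manifest JSON."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, mask, lab) in enumerate(zip(ds.images, ds.masks, ds.labels)):
        name = f"tongue_{i:05d}.png"
        Image.fromarray(img).save(outdir / "images" / name)
        Image.fromarray((mask * 255).astype(np.uint8)).save(outdir / "masks" / name)
        rows.append((name, int(lab)))
    with open(outdir / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label"])
        writer.writerows(rows)
    manifest = {"n": len(ds), "params": asdict(ds.params) if ds.params else None}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def load_image_dataset(indir: str | Path) -> LabeledImageSet:
    indir = Path(indir)
    images, masks, labels = [], [], []
    with open(indir / "labels.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            img = np.asarray(Image.open(indir / "images" / row["filename"]).convert("RGB"))
            m = np.asarray(Image.open(indir / "masks" / row["filename"]).convert("L"))
            images.append(img)
            masks.append((m > 127).astype(np.uint8))
            labels.append(int(row["label"]))
    params = None
    manifest = indir / "manifest.json"
    if manifest.exists():
        raw = json.loads(manifest.read_text()).get("params")
        if raw is not None:
            params = SyntheticImageParams(**raw)
    return LabeledImageSet(images, masks, np.asarray(labels), params)
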