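"""Branch B: a residual CNN image classifier with Shuttle Attention.

A shuttle block partitions the channels of a feature map into g groups,
halves each group, runs channel attention (global average pooling ->
single linear layer -> sigmoid) on one half and spatial attention (group
normalisation -> 1x1 convolution -> sigmoid) on the other, concatenates
everything back and finishes with a channel-shuffle permutation so
information flows across groups at zero parameter cost.

Two backbones are provided: ``resnet50`` (bottleneck stages 3-4-6-3, for
full-size 224x224 inputs) and ``resnet-mini`` (three basic-block stages of
16/32/64 channels on 64x64 inputs) for desk-scale experiments.  A shuttle
block sits inside every residual unit after the last convolution, before
the skip addition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize

from ._nn import (
    Tensor, Module, Linear, Conv2d, BatchNorm2d, GroupNorm,
    Adam, cosine_lr, soft_cross_entropy, concat,
)
from .cles import smooth_labels

__all__ = [
    "ShuttleConfig", "group_split", "channel_shuffle",
    "ChannelAttention", "SpatialAttention", "ShuttleBlock",
    "build_model", "preprocess_images", "predict_proba", "train_cnn_branch",
]


@dataclass(frozen=True)
class ShuttleConfig:
    groups: int = 4
    backbone: str = "resnet-mini"      # {"resnet-mini", "resnet50"}
    input_size: int = 64
    learning_rate: float = 1e-3        # resnet50 profile uses 1e-4 (see below)
    epochs: int = 5
    batch_size: int = 32
    seed: int = 0
    double_channel_attention: bool = False  # literal two-channel-attention variant

    @staticmethod
    def resnet50_profile(**overrides) -> "ShuttleConfig":
        """Published-style full-scale settings: 224 px, batch 32, lr 1e-4
        with cosine annealing."""
        base = dict(backbone="resnet50", input_size=224, learning_rate=1e-4,
                    epochs=50, batch_size=32)
        base.update(overrides)
        return ShuttleConfig(**base)


# -- shuttle primitives ------------------------------------------------------

def group_split(x: np.ndarray | Tensor, g: int) -> list[tuple]:
    """Partition channels into g contiguous groups, each halved in two.

    Returns a list of (first_half, second_half) per group; concatenating
    all pieces in order reproduces the input exactly.
    """
    c = x.shape[1]
    if c % (2 * g):
        raise ValueError(f"channel count {c} not divisible by 2*groups={2 * g}")
    size = c // g
    half = size // 2
    out = []
    for k in range(g):
        lo = k * size
        if isinstance(x, Tensor):
            out.append((x[:, lo:lo + half], x[:, lo + half:lo + size]))
        else:
            out.append((x[:, lo:lo + half], x[:, lo + half:lo + size]))
    return out


def channel_shuffle(x: np.ndarray | Tensor, g: int):
    """Channel permutation i -> (i mod g) * (C/g) + floor(i/g).

    Implemented as reshape (g, C/g) -> transpose -> flatten; values are
    untouched.  g=1 is the identity.
    """
    n, c = x.shape[0], x.shape[1]
    if c % g:
        raise ValueError(f"channel count {c} not divisible by groups={g}")
    rest = x.shape[2:]
    if isinstance(x, Tensor):
        out = x.reshape(n, g, c // g, *rest)
        axes = (0, 2, 1) + tuple(range(3, 3 + len(rest)))
        return out.transpose(axes).reshape(n, c, *rest)
    out = x.reshape(n, g, c // g, *rest)
    return np.ascontiguousarray(out.swapaxes(1, 2)).reshape(n, c, *rest)


class ChannelAttention(Module):
    """Per-channel reweighting: sigmoid(Linear(GAP(x))) * x."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.linear = Linear(channels, channels, rng)

    def __call__(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        gap = x.mean(axis=(2, 3))             # (N, C)
        w = self.linear(gap).sigmoid()        # in (0, 1)
        return x * w.reshape(n, c, 1, 1)


class SpatialAttention(Module):
    """Per-position reweighting: sigmoid(Conv1x1(GroupNorm(x))) * x."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.norm = GroupNorm(1, channels)
        self.conv = Conv2d(channels, 1, (1, 1), rng)

    def __call__(self, x: Tensor) -> Tensor:
        w = self.conv(self.norm(x)).sigmoid()  # (N, 1, H, W)
        return x * w


class ShuttleBlock(Module):
    """Grouped parallel channel/spatial attention ending in channel shuffle."""

    def __init__(self, channels: int, groups: int, rng: np.random.Generator,
                 double_channel_attention: bool = False):
        super().__init__()
        if channels % (2 * groups):
            raise ValueError("channels must be divisible by 2*groups")
        self.groups = groups
        half = channels // (2 * groups)
        # attention weights are shared across groups (lightweight design)
        self.channel_attn = ChannelAttention(half, rng)
        if double_channel_attention:
            self.second_attn: Module = ChannelAttention(half, rng)
        else:
            self.second_attn = SpatialAttention(half, rng)

    def __call__(self, x: Tensor) -> Tensor:
        pieces = []
        for x1, x2 in group_split(x, self.groups):
            pieces.append(concat([self.channel_attn(x1), self.second_attn(x2)], axis=1))
        return channel_shuffle(concat(pieces, axis=1), self.groups)


# -- backbone ----------------------------------------------------------------

class _BasicBlock(Module):
    """conv3x3-BN-ReLU-conv3x3-BN -> shuttle -> +skip -> ReLU."""

    def __init__(self, cin: int, cout: int, stride: int, groups: int,
                 rng: np.random.Generator, double_ca: bool):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, (3, 3), rng, stride=(stride, stride),
                            padding=(1, 1), bias=False)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, (3, 3), rng, padding=(1, 1), bias=False)
        self.bn2 = BatchNorm2d(cout)
        self.shuttle = ShuttleBlock(cout, groups, rng, double_ca)
        if stride != 1 or cin != cout:
            self.down_conv = Conv2d(cin, cout, (1, 1), rng,
                                    stride=(stride, stride), bias=False)
            self.down_bn = BatchNorm2d(cout)
        else:
            self.down_conv = None
            self.down_bn = None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.shuttle(self.bn2(self.conv2(h)))
        skip = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (h + skip).relu()


class _Bottleneck(Module):
    """1x1-3x3-1x1 bottleneck unit with a shuttle block before the skip."""

    expansion = 4

    def __init__(self, cin: int, cmid: int, stride: int, groups: int,
                 rng: np.random.Generator, double_ca: bool):
        super().__init__()
        cout = cmid * self.expansion
        self.conv1 = Conv2d(cin, cmid, (1, 1), rng, bias=False)
        self.bn1 = BatchNorm2d(cmid)
        self.conv2 = Conv2d(cmid, cmid, (3, 3), rng, stride=(stride, stride),
                            padding=(1, 1), bias=False)
        self.bn2 = BatchNorm2d(cmid)
        self.conv3 = Conv2d(cmid, cout, (1, 1), rng, bias=False)
        self.bn3 = BatchNorm2d(cout)
        self.shuttle = ShuttleBlock(cout, groups, rng, double_ca)
        if stride != 1 or cin != cout:
            self.down_conv = Conv2d(cin, cout, (1, 1), rng,
                                    stride=(stride, stride), bias=False)
            self.down_bn = BatchNorm2d(cout)
        else:
            self.down_conv = None
            self.down_bn = None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h)).relu()
        h = self.shuttle(self.bn3(self.conv3(h)))
        skip = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (h + skip).relu()


class ShuttleResNet(Module):
    def __init__(self, config: ShuttleConfig, use_shuttle: bool = True):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        g = config.groups
        dca = config.double_channel_attention
        self.use_shuttle = use_shuttle
        if config.backbone == "resnet-mini":
            self.stem = Conv2d(3, 16, (3, 3), rng, stride=(2, 2),
                               padding=(1, 1), bias=False)
            self.stem_bn = BatchNorm2d(16)
            self.blocks = [
                _BasicBlock(16, 16, 1, g, rng, dca),
                _BasicBlock(16, 32, 2, g, rng, dca),
                _BasicBlock(32, 64, 2, g, rng, dca),
            ]
            feat = 64
        elif config.backbone == "resnet50":
            self.stem = Conv2d(3, 64, (7, 7), rng, stride=(2, 2),
                               padding=(3, 3), bias=False)
            self.stem_bn = BatchNorm2d(64)
            self.blocks = []
            cin = 64
            for cmid, n_blocks, stride in ((64, 3, 1), (128, 4, 2),
                                           (256, 6, 2), (512, 3, 2)):
                for b in range(n_blocks):
                    self.blocks.append(_Bottleneck(
                        cin, cmid, stride if b == 0 else 1, g, rng, dca))
                    cin = cmid * _Bottleneck.expansion
            feat = cin
        else:
            raise ValueError(f"unknown backbone {config.backbone!r}")
        if not use_shuttle:
            for blk in self.blocks:
                blk.shuttle = _Identity()
        self.head = Linear(feat, 2, rng)

    def logits(self, x: Tensor) -> Tensor:
        h = self.stem_bn(self.stem(x)).relu()
        for blk in self.blocks:
            h = blk(h)
        pooled = h.mean(axis=(2, 3))
        return self.head(pooled)

    def __call__(self, x: Tensor) -> Tensor:
        return self.logits(x).softmax(axis=1)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def save(self, path: str | Path):
        arrays = {f"a{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(Path(path), config=json.dumps(asdict(self.config)),
                 use_shuttle=np.array(self.use_shuttle), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ShuttleResNet":
        with np.load(Path(path), allow_pickle=False) as data:
            cfg = ShuttleConfig(**json.loads(str(data["config"])))
            model = cls(cfg, use_shuttle=bool(data["use_shuttle"]))
            for i, tgt in enumerate(model.state_arrays()):
                tgt[...] = data[f"a{i}"]
        return model


class _Identity(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return x


def build_model(config: ShuttleConfig, use_shuttle: bool = True) -> ShuttleResNet:
    """Residual CNN with a shuttle block in every residual unit."""
    return ShuttleResNet(config, use_shuttle=use_shuttle)


# -- training ----------------------------------------------------------------

def preprocess_images(images, masks, size: int) -> np.ndarray:
    """Zero the background, rescale to [0, 1], resize, channels-first."""
    out = np.empty((len(images), 3, size, size))
    for i, (img, mask) in enumerate(zip(images, masks)):
        arr = np.asarray(img, float) / 255.0
        arr = arr * (np.asarray(mask) > 0)[:, :, None]
        if arr.shape[:2] != (size, size):
            arr = resize(arr, (size, size), order=1, anti_aliasing=True)
        out[i] = arr.transpose(2, 0, 1)
    return out


def predict_proba(model: ShuttleResNet, images, masks,
                  batch_size: int = 64) -> np.ndarray:
    """At-risk (class-1) probability per image, evaluation mode."""
    x = preprocess_images(images, masks, model.config.input_size)
    model.eval()
    probs = []
    for start in range(0, len(x), batch_size):
        p = model(Tensor(x[start:start + batch_size])).data
        probs.append(p[:, 1])
    return np.concatenate(probs)


def train_cnn_branch(images, masks, labels, config: ShuttleConfig,
                     eval_images=None, eval_masks=None,
                     use_shuttle: bool = True
                     ) -> tuple[ShuttleResNet, np.ndarray]:
    """Train the CNN branch and return (model, scores).

    ``labels`` may be hard or label-smoothed soft targets.  Training uses
    Adam with a cosine-annealed learning rate.  ``scores`` are class-1
    probabilities on the evaluation images if given (held-out scores for
    fusion), else on the training images.
    """
    y = np.asarray(labels, float)
    if y.ndim == 1:
        if len(np.unique(y)) < 2:
            raise ValueError("labels contain a single class")
        y = smooth_labels(y.astype(int), 0.0, 2)
    x = preprocess_images(images, masks, config.input_size)
    model = build_model(config, use_shuttle=use_shuttle)
    model.train()
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = len(x)
    bs = min(config.batch_size, n)
    steps_per_epoch = max(1, (n + bs - 1) // bs)
    total_steps = config.epochs * steps_per_epoch
    step = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            if len(idx) < 2:
                continue
            opt.lr = cosine_lr(config.learning_rate, step, total_steps)
            logits = model.logits(Tensor(x[idx]))
            loss = soft_cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            step += 1
        model.training_log = getattr(model, "training_log", [])
        model.training_log.append(epoch_loss / n)
    model.eval()
    if eval_images is not None:
        scores = predict_proba(model, eval_images, eval_masks)
    else:
        scores = predict_proba(model, images, masks)
    return model, scores
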