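"""Neural-network layers built on the tensor engine.

Initialisation takes an explicit numpy Generator so every model in the
package is bit-reproducible from a single integer seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module", "Linear", "Conv1d", "Conv2d",
    "BatchNorm1d", "BatchNorm2d", "GroupNorm",
]


class Module:
    """Base class: tracks parameters, submodules and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def _set_mode(self, training: bool):
        self.training = training
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v._set_mode(training)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item._set_mode(training)

    def train(self):
        self._set_mode(True)
        return self

    def eval(self):
        self._set_mode(False)
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays (parameters + running stats) in a stable order."""
        arrays: list[np.ndarray] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor):
                arrays.append(v.data)
            elif isinstance(v, np.ndarray):
                arrays.append(v)
            elif isinstance(v, Module):
                arrays.extend(v.state_arrays())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        arrays.extend(item.state_arrays())
        return arrays


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (in_features + out_features))  # Glorot uniform
        self.weight = Tensor(rng.uniform(-bound, bound, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel_size: tuple[int, int],
                 rng: np.random.Generator, stride: tuple[int, int] = (1, 1),
                 padding: tuple[int, int] = (0, 0), bias: bool = True):
        super().__init__()
        kh, kw = kernel_size
        fan_in = in_ch * kh * kw
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Tensor(rng.normal(0.0, std, (out_ch, in_ch, kh, kw)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.padding)


class Conv1d(Module):
    """1-D convolution over the feature axis, implemented as a 1×K Conv2d."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 rng: np.random.Generator, padding: int = 0, bias: bool = True):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, (1, kernel_size), rng,
                           padding=(0, padding), bias=bias)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (N, C, L) -> (N, C, 1, L) -> conv -> (N, C', L)
        n, c, length = x.shape
        out = self.conv(x.reshape(n, c, 1, length))
        return out.reshape(out.shape[0], out.shape[1], out.shape[3])


class _Norm(Module):
    def __init__(self, num_features: int, eps: float, momentum: float):
        super().__init__()
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)


class BatchNorm1d(_Norm):
    """Batch normalisation over (N, F) activations."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__(num_features, eps, momentum)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
        else:
            mu = Tensor(self.running_mean[None, :])
            var = Tensor(self.running_var[None, :])
        xhat = (x - mu) * (var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class BatchNorm2d(_Norm):
    """Batch normalisation over (N, C, H, W) activations, per channel."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__(num_features, eps, momentum)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
        else:
            mu = Tensor(self.running_mean[None, :, None, None])
            var = Tensor(self.running_var[None, :, None, None])
        xhat = (x - mu) * (var + self.eps) ** -0.5
        gamma = self.gamma.reshape(1, -1, 1, 1)
        beta = self.beta.reshape(1, -1, 1, 1)
        return xhat * gamma + beta


class GroupNorm(Module):
    """Group normalisation over (N, C, H, W): per-sample, per-group statistics."""

    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        super().__init__()
        if num_channels % num_groups:
            raise ValueError("num_channels must be divisible by num_groups")
        self.num_groups = num_groups
        self.gamma = Tensor(np.ones(num_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(num_channels), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.num_groups
        xg = x.reshape(n, g, (c // g) * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2.0).mean(axis=2, keepdims=True)
        xhat = ((xg - mu) * (var + self.eps) ** -0.5).reshape(n, c, h, w)
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)
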