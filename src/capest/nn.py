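"""Neural-network building blocks on top of :mod:`capest.autodiff`.

Layers follow the conventions of single-stage detector codebases: NCHW
layout, convolutions with optional bias, group normalization in the head
towers, frozen batch-norm in the pretrained-style backbone, and per-level
learnable scalar scales for the regression branch.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Tensor

__all__ = [
    "Parameter", "Module", "Sequential", "Conv2d", "GroupNorm",
    "FrozenBatchNorm2d", "ReLU", "MaxPool2d", "Scale",
    "upsample_nearest2x", "SGD",
]


class Parameter(Tensor):
    """A leaf tensor registered by :class:`Module`.

    ``trainable=False`` marks parameters that exist in the architecture but
    are kept frozen during fine-tuning (frozen backbone stages, frozen BN
    affine transforms); they are excluded from optimizer updates and from
    trainable-parameter counts.
    """

    __slots__ = ("trainable", "lr_mult")

    def __init__(self, data, trainable: bool = True, dtype=None,
                 lr_mult: float = 1.0):
        super().__init__(data, requires_grad=trainable, dtype=dtype)
        self.trainable = trainable
        self.lr_mult = lr_mult


class Module:
    """Container with recursive parameter discovery (attribute-based)."""

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def trainable_parameters(self):
        return [p for p in self.parameters() if p.trainable]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{key}.{i}", item))
        return out

    def num_parameters(self, trainable_only: bool = True) -> int:
        params = self.trainable_parameters() if trainable_only else self.parameters()
        return int(sum(p.data.size for p in params))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in checkpoint: {sorted(missing)}")
        for k, p in own.items():
            if state[k].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{state[k].shape} vs {p.data.shape}")
            p.data = np.asarray(state[k], dtype=p.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Conv2d(Module):
    """2-D convolution (cross-correlation) via im2col + GEMM."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 trainable: bool = True, rng: np.random.Generator | None = None,
                 init_std: float | None = None):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        std = init_std if init_std is not None else math.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, size=(out_channels, in_channels,
                                       kernel_size, kernel_size))
        self.weight = Parameter(w.astype(np.float32), trainable=trainable)
        self.bias = (Parameter(np.zeros(out_channels, dtype=np.float32),
                               trainable=trainable) if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        k, s, p = self.kernel_size, self.stride, self.padding
        n, c, h, wd = x.data.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
        hp, wp = xp.shape[2], xp.shape[3]
        ho = (hp - k) // s + 1
        wo = (wp - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (N, C, Ho, Wo, k, k) -> (N*Ho*Wo, C*k*k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k)
        wmat = w.data.reshape(self.out_channels, c * k * k)
        out = cols @ wmat.T
        if b is not None:
            out = out + b.data
        out_data = np.ascontiguousarray(
            out.reshape(n, ho, wo, self.out_channels).transpose(0, 3, 1, 2))

        parents = (x, w) if b is None else (x, w, b)

        def backward(g):
            g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(
                n * ho * wo, self.out_channels)
            grads = []
            if x.requires_grad:
                dcols = g2 @ wmat
                dwin = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
                dxp = np.zeros((n, c, hp, wp), dtype=g.dtype)
                for ki in range(k):
                    for kj in range(k):
                        dxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += \
                            dwin[:, :, :, :, ki, kj]
                dx = dxp[:, :, p:hp - p, p:wp - p] if p else dxp
                grads.append((x, dx))
            if w.requires_grad:
                grads.append((w, (g2.T @ cols).reshape(w.data.shape)))
            if b is not None and b.requires_grad:
                grads.append((b, g2.sum(axis=0)))
            return grads

        return Tensor._make(out_data, parents, backward)


class GroupNorm(Module):
    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        if num_channels % num_groups:
            raise ValueError("channels must divide evenly into groups")
        self.num_groups = num_groups
        self.num_channels = num_channels
        self.eps = eps
        self.weight = Parameter(np.ones(num_channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        g = self.num_groups
        xg = x.reshape(n, g, (c // g) * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        d = xg - mu
        var = (d * d).mean(axis=2, keepdims=True)
        xhat = d * ((var + self.eps) ** -0.5)
        xhat = xhat.reshape(n, c, h, w)
        return xhat * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)


class FrozenBatchNorm2d(Module):
    """Batch-norm with fixed statistics and frozen affine parameters.

    Mirrors the caffe-style backbone convention where BN layers act as fixed
    per-channel affine transforms during detector fine-tuning.
    """

    def __init__(self, num_channels: int, eps: float = 1e-5):
        self.num_channels = num_channels
        self.eps = eps
        self.weight = Parameter(np.ones(num_channels, dtype=np.float32),
                                trainable=False)
        self.bias = Parameter(np.zeros(num_channels, dtype=np.float32),
                              trainable=False)
        # running statistics are buffers, not parameters
        self.running_mean = np.zeros(num_channels, dtype=np.float32)
        self.running_var = np.ones(num_channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        c = self.num_channels
        scale = self.weight.data / np.sqrt(self.running_var + self.eps)
        shift = self.bias.data - self.running_mean * scale
        return x * Tensor(scale.reshape(1, c, 1, 1)) + Tensor(shift.reshape(1, c, 1, 1))


class BatchNorm2d(FrozenBatchNorm2d):
    """Trainable-affine variant (statistics still fixed; the detectors here
    fine-tune with batch size 2 where true batch statistics are unusable)."""

    def __init__(self, num_channels: int, eps: float = 1e-5):
        super().__init__(num_channels, eps)
        self.weight = Parameter(np.ones(num_channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_channels, dtype=np.float32))


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel_size, self.stride, self.padding
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf) if p else x.data
        n, c, hp, wp = xp.shape
        ho = (hp - k) // s + 1
        wo = (wp - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(n, c, ho, wo, k * k)
        arg = flat.argmax(axis=-1)
        out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

        def backward(g):
            dxp = np.zeros((n, c, hp, wp), dtype=g.dtype)
            ki, kj = np.divmod(arg, k)
            ii = (np.arange(ho)[None, None, :, None] * s + ki)
            jj = (np.arange(wo)[None, None, None, :] * s + kj)
            nn_ = np.arange(n)[:, None, None, None]
            cc = np.arange(c)[None, :, None, None]
            np.add.at(dxp, (nn_, cc, ii, jj), g)
            dx = dxp[:, :, p:hp - p, p:wp - p] if p else dxp
            return ((x, dx),)

        return Tensor._make(np.ascontiguousarray(out_data), (x,), backward)


class Scale(Module):
    """Learnable scalar multiplier (one per pyramid level in the head)."""

    def __init__(self, init: float = 1.0):
        self.scale = Parameter(np.array(init, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x * self.scale


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x up-sampling: each pixel becomes a 2x2 block."""
    n, c, h, w = x.data.shape
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        return ((x, g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))),)

    return Tensor._make(out_data, (x,), backward)


class SGD:
    """Stochastic gradient descent with momentum and weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * getattr(p, "lr_mult", 1.0) * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
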