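"""Coordinate attention: direction-aware channel gating for feature maps.

The block factorizes global pooling into two directional pools — one along
the width (per-row descriptors) and one along the height (per-column
descriptors) — so the resulting attention retains positional information.
The pooled descriptors are concatenated along the spatial axis, passed
through a shared 1x1 bottleneck transform with a nonlinearity, split back,
and restored to the input channel count by two independent 1x1 transforms
whose sigmoid outputs gate the rows and columns of the input:

    o[l, i, j] = x[l, i, j] * gh[l, i] * gw[l, j]

Because every gate lies strictly in (0, 1), the block is an elementwise
contraction of its input.

Operations accept either a single feature map (C, H, W) or a batch
(N, C, H, W); the module form :class:`CABlock` is what the pyramid uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concatenate
from .errors import ConfigurationError, ValidationError
from .nn import Conv2d, Module, BatchNorm2d

__all__ = ["DirectionalDescriptors", "CAGates", "CABlock",
           "pool_directional", "ca_gates", "ca_apply", "ca_block"]


@dataclass
class DirectionalDescriptors:
    """Per-height (``zh``: ... x C x H) and per-width (``zw``: ... x C x W)
    channel means of a feature map."""

    zh: Tensor
    zw: Tensor


@dataclass
class CAGates:
    """Sigmoid row gates (``gh``: ... x C x H) and column gates
    (``gw``: ... x C x W); every entry lies strictly in (0, 1)."""

    gh: Tensor
    gw: Tensor


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def pool_directional(x) -> DirectionalDescriptors:
    """Directional average pooling with kernels (H, 1) and (1, W).

    ``zh[..., l, h]`` is the mean of row ``h`` of channel ``l``;
    ``zw[..., l, w]`` is the mean of column ``w``.
    """
    x = _as_tensor(x)
    if x.ndim not in (3, 4):
        raise ValidationError(f"expected (C,H,W) or (N,C,H,W), got {x.shape}")
    if not np.all(np.isfinite(x.data)):
        raise ValidationError("feature map contains non-finite values")
    zh = x.mean(axis=-1)          # average over width  -> (..., C, H)
    zw = x.mean(axis=-2)          # average over height -> (..., C, W)
    return DirectionalDescriptors(zh=zh, zw=zw)


def ca_gates(z: DirectionalDescriptors, p: "CABlock") -> CAGates:
    """Joint 1x1 bottleneck over the concatenated descriptors, split back,
    and restored per axis through sigmoid transforms."""
    zh, zw = z.zh, z.zw
    squeeze = zh.ndim == 2
    if squeeze:
        zh = zh.reshape(1, *zh.shape)
        zw = zw.reshape(1, *zw.shape)
    c = zh.shape[1]
    if c != p.channels:
        raise ConfigurationError(
            f"descriptor channels {c} do not match block channels {p.channels}")
    h, w = zh.shape[2], zw.shape[2]
    # spatial-axis concatenation -> (N, C, H+W, 1) so 1x1 convs apply directly
    f = concatenate([zh, zw], axis=2).reshape(zh.shape[0], c, h + w, 1)
    f = p.conv_joint(f)
    if p.norm is not None:
        f = p.norm(f)
    f = p.activation(f)
    fh = f[:, :, :h, :]
    fw = f[:, :, h:, :]
    gh = p.conv_h(fh).sigmoid().reshape(zh.shape[0], c, h)
    gw = p.conv_w(fw).sigmoid().reshape(zw.shape[0], c, w)
    if squeeze:
        gh = gh.reshape(c, h)
        gw = gw.reshape(c, w)
    return CAGates(gh=gh, gw=gw)


def ca_apply(x, g: CAGates) -> Tensor:
    """Reweight: ``o[l,i,j] = x[l,i,j] * gh[l,i] * gw[l,j]``."""
    x = _as_tensor(x)
    gh, gw = g.gh, g.gw
    if x.shape[:-1] != gh.shape or x.shape[:-2] + x.shape[-1:] != gw.shape:
        raise ValidationError(
            f"gate shapes {gh.shape}/{gw.shape} incompatible with map {x.shape}")
    return x * gh.reshape(*gh.shape, 1) * gw.reshape(*gw.shape[:-1], 1, gw.shape[-1])


def ca_block(x, p: "CABlock") -> Tensor:
    """Full block: pool, gate, reweight (differentiable end to end)."""
    return ca_apply(x, ca_gates(pool_directional(x), p))


class CABlock(Module):
    """Learnable coordinate-attention block.

    Parameters
    ----------
    channels:
        Input/output channel count C.
    reduction:
        Bottleneck reduction ratio r; the joint transform maps C channels to
        ``ceil(C / r)``.  The default 3.5 makes the three pyramid blocks add
        about 0.17 M parameters at C = 256 (57,418 each).
    activation:
        Intermediate nonlinearity after the joint transform (default ReLU).
    use_norm:
        Insert a trainable-affine batch-norm after the joint transform.
    """

    def __init__(self, channels: int, reduction: float = 3.5,
                 activation=None, use_norm: bool = False,
                 rng: np.random.Generator | None = None):
        if reduction < 1:
            raise ConfigurationError("reduction ratio must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.reduction = reduction
        self.hidden = max(1, math.ceil(channels / reduction))
        self.conv_joint = Conv2d(channels, self.hidden, 1, rng=rng)
        self.conv_h = Conv2d(self.hidden, channels, 1, rng=rng)
        self.conv_w = Conv2d(self.hidden, channels, 1, rng=rng)
        self.norm = BatchNorm2d(self.hidden) if use_norm else None
        self.activation = activation or (lambda t: t.relu())

    def forward(self, x) -> Tensor:
        return ca_block(x, self)
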