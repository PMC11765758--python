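"""Coordinate-attention feature pyramid (CAFPN).

Builds the standard top-down pyramid — 1x1 lateral projections to a uniform
width, nearest 2x up-sampling, elementwise addition, and a 3x3 smoothing
convolution after each fusion — with an optional coordinate-attention block
inserted on the top-down path:

    plain FPN:   Y_i = C_i(X_i) + Up(Y_{i+1})
    CAFPN:       Y_i = C_i(X_i) + CA(Up(Y_{i+1}))

Three CA blocks are used, one per fused level: two modulate the up-sampled
maps entering the two top-down merges, and one modulates the projected
deepest map that seeds the pyramid.  With attention disabled the module is
numerically identical to the plain pyramid (same weights, same outputs).

Extra levels P6/P7 are produced by stride-2 3x3 convolutions from P5 (the
single-stage detector convention), giving strides 8, 16, 32, 64, 128.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .coordinate_attention import CABlock
from .errors import ConfigurationError, ValidationError
from .nn import Conv2d, Module, upsample_nearest2x

__all__ = ["FpnConfig", "CAFPN", "lateral_project", "upsample2x", "fuse_level",
           "build_pyramid"]


@dataclass
class FpnConfig:
    """Plumbing options for the pyramid."""

    width: int = 256
    use_ca: bool = True
    ca_reduction: float = 3.5
    extra_levels: int = 2
    smooth_kernel: int = 3

    def __post_init__(self):
        if self.width <= 0:
            raise ConfigurationError("pyramid width must be positive")
        if self.extra_levels < 0:
            raise ConfigurationError("extra_levels must be >= 0")


def upsample2x(y) -> Tensor:
    """Nearest-neighbour 2x up-sampling (each pixel -> 2x2 block)."""
    y = y if isinstance(y, Tensor) else Tensor(np.asarray(y, dtype=np.float32))
    if y.ndim == 3:
        return upsample_nearest2x(y.reshape(1, *y.shape)).reshape(
            y.shape[0], 2 * y.shape[1], 2 * y.shape[2])
    return upsample_nearest2x(y)


def _crop_to(up: Tensor, h: int, w: int) -> Tensor:
    """Trim an up-sampled map to the lateral's exact spatial size (odd input
    grids up-sample one row/column too far)."""
    uh, uw = up.shape[-2], up.shape[-1]
    if uh < h or uw < w or uh > h + 1 or uw > w + 1:
        raise ValidationError(
            f"up-sampled size {(uh, uw)} incompatible with lateral {(h, w)}")
    if uh == h and uw == w:
        return up
    return up[..., :h, :w]


def lateral_project(xi, conv: Conv2d) -> Tensor:
    """1x1 projection of a backbone map to the pyramid width."""
    xi = xi if isinstance(xi, Tensor) else Tensor(np.asarray(xi, dtype=np.float32))
    squeeze = xi.ndim == 3
    if squeeze:
        xi = xi.reshape(1, *xi.shape)
    out = conv(xi)
    return out.reshape(out.shape[1:]) if squeeze else out


def fuse_level(lateral: Tensor, upper: Tensor, cfg: FpnConfig,
               ca: CABlock | None = None) -> Tensor:
    """One top-down merge: ``lateral + [CA](Up(upper))``."""
    up = upsample2x(upper)
    up = _crop_to(up, lateral.shape[-2], lateral.shape[-1])
    if cfg.use_ca:
        if ca is None:
            raise ConfigurationError("use_ca is set but no CA block supplied")
        up = ca(up)
    return lateral + up


class CAFPN(Module):
    """The pyramid module; consumes (C3, C4, C5), emits P3..P(3+2+extras)."""

    def __init__(self, in_channels, cfg: FpnConfig | None = None,
                 rng: np.random.Generator | None = None):
        if len(in_channels) < 3:
            raise ConfigurationError("need three backbone levels (C3, C4, C5)")
        rng = rng or np.random.default_rng(0)
        cfg = cfg or FpnConfig()
        self.cfg = cfg
        w = cfg.width
        self.laterals = [Conv2d(c, w, 1, rng=rng) for c in in_channels[:3]]
        pad = cfg.smooth_kernel // 2
        self.smooth = [Conv2d(w, w, cfg.smooth_kernel, padding=pad, rng=rng)
                       for _ in range(3)]
        self.extras = [Conv2d(w, w, 3, stride=2, padding=1, rng=rng)
                       for _ in range(cfg.extra_levels)]
        if cfg.use_ca:
            self.ca_blocks = [CABlock(w, reduction=cfg.ca_reduction, rng=rng)
                              for _ in range(3)]
        else:
            self.ca_blocks = []

    @property
    def strides(self):
        return tuple(8 * 2 ** i for i in range(3 + self.cfg.extra_levels))

    def set_identity_smoothing(self):
        """Make each smoothing conv the identity (tests of the fusion path)."""
        for conv in self.smooth:
            k = conv.kernel_size
            w = np.zeros_like(conv.weight.data)
            for c in range(conv.out_channels):
                w[c, c, k // 2, k // 2] = 1.0
            conv.weight.data = w
            if conv.bias is not None:
                conv.bias.data = np.zeros_like(conv.bias.data)

    def forward(self, feats):
        return build_pyramid(feats, self.cfg, self)


def build_pyramid(feats, cfg: FpnConfig, module: CAFPN):
    """Top-down pass producing the list of pyramid levels (fine to coarse)."""
    if len(feats) < 3:
        raise ConfigurationError("need three backbone levels")
    laterals = [module.laterals[i](feats[i]) for i in range(3)]

    top = laterals[2]
    if cfg.use_ca:
        top = module.ca_blocks[2](top)
    ys = [None, None, top]
    for i in (1, 0):
        ca = module.ca_blocks[i] if cfg.use_ca else None
        ys[i] = fuse_level(laterals[i], ys[i + 1], cfg, ca)

    pyramid = [module.smooth[i](ys[i]) for i in range(3)]
    prev = pyramid[2]
    for j, conv in enumerate(module.extras):
        prev = conv(prev if j == 0 else prev.relu())
        pyramid.append(prev)
    return pyramid
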