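"""Multi-scale backbones.

Two backbones are provided behind the same interface (a callable returning
the three feature maps C3, C4, C5 at strides 8, 16, 32):

* :class:`ResNet50` — the standard 50-layer residual network used by
  single-stage detectors, reproduced stage by stage so that parameter
  accounting matches the published detector family exactly.  Supports the
  usual fine-tuning conventions: freezing the stem and a number of leading
  stages, and caffe-style frozen batch-norm throughout.
* :class:`TinyBackbone` — a five-convolution desk-scale backbone for
  CPU-sized experiments on small synthetic scenes.

Backbone weights are randomly initialized; no pretrained download is
required or attempted.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .nn import (BatchNorm2d, Conv2d, FrozenBatchNorm2d, GroupNorm, MaxPool2d,
                 Module, ReLU, Sequential)

__all__ = ["ResNet50", "TinyBackbone", "build_backbone"]


class _Bottleneck(Module):
    expansion = 4

    def __init__(self, in_ch, mid_ch, stride, norm_layer, trainable, rng):
        out_ch = mid_ch * self.expansion
        conv = lambda i, o, k, s, p: Conv2d(i, o, k, stride=s, padding=p,
                                            bias=False, trainable=trainable, rng=rng)
        self.conv1 = conv(in_ch, mid_ch, 1, 1, 0)
        self.bn1 = norm_layer(mid_ch)
        self.conv2 = conv(mid_ch, mid_ch, 3, stride, 1)
        self.bn2 = norm_layer(mid_ch)
        self.conv3 = conv(mid_ch, out_ch, 1, 1, 0)
        self.bn3 = norm_layer(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = conv(in_ch, out_ch, 1, stride, 0)
            self.down_bn = norm_layer(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x):
        identity = x
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        if self.down_conv is not None:
            identity = self.down_bn(self.down_conv(x))
        return (out + identity).relu()


class ResNet50(Module):
    """ResNet-50 feature extractor returning (C3, C4, C5).

    Parameters
    ----------
    frozen_stages:
        ``-1`` trains everything; ``0`` freezes the stem; ``1`` additionally
        freezes the first residual stage (the common detector default).
    norm_trainable:
        When ``False`` (caffe-style), every batch-norm affine transform is
        frozen; when ``True``, BN affine parameters train everywhere except
        in frozen stages.
    """

    out_channels = (512, 1024, 2048)

    def __init__(self, frozen_stages: int = 1, norm_trainable: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        blocks = (3, 4, 6, 3)
        mids = (64, 128, 256, 512)

        stem_trainable = frozen_stages < 0
        stem_norm = BatchNorm2d if (norm_trainable and stem_trainable) else FrozenBatchNorm2d
        self.conv1 = Conv2d(3, 64, 7, stride=2, padding=3, bias=False,
                            trainable=stem_trainable, rng=rng)
        self.bn1 = stem_norm(64)
        self.maxpool = MaxPool2d(3, stride=2, padding=1)

        self.stages = []
        in_ch = 64
        for si, (n, mid) in enumerate(zip(blocks, mids)):
            trainable = si + 1 > frozen_stages
            norm = BatchNorm2d if (norm_trainable and trainable) else FrozenBatchNorm2d
            stage = []
            for bi in range(n):
                stride = 1 if (si == 0 or bi > 0) else 2
                stage.append(_Bottleneck(in_ch, mid, stride, norm, trainable, rng))
                in_ch = mid * _Bottleneck.expansion
            self.stages.append(Sequential(*stage))

    def forward(self, x: Tensor):
        x = self.bn1(self.conv1(x)).relu()
        x = self.maxpool(x)
        feats = []
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return feats[1], feats[2], feats[3]  # strides 8, 16, 32


class TinyBackbone(Module):
    """Five stride-2 convolutions with group-norm; returns C3, C4, C5.

    Designed for 128x128 synthetic scenes: feature maps at strides 8/16/32
    are 16x16, 8x8 and 4x4.
    """

    def __init__(self, widths=(16, 24, 32, 48, 64),
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        if len(widths) != 5:
            raise ValueError("TinyBackbone needs five stage widths")
        self.out_channels = tuple(widths[2:])
        chans = (3,) + tuple(widths)
        self.blocks = []
        for i in range(5):
            self.blocks.append(Sequential(
                Conv2d(chans[i], chans[i + 1], 3, stride=2, padding=1,
                       bias=False, rng=rng),
                GroupNorm(min(8, chans[i + 1]), chans[i + 1]),
                ReLU(),
            ))

    def forward(self, x: Tensor):
        feats = []
        for block in self.blocks:
            x = block(x)
            feats.append(x)
        return feats[2], feats[3], feats[4]


def build_backbone(name: str, rng=None, **kwargs):
    if name == "resnet50":
        return ResNet50(rng=rng, **kwargs)
    if name == "tiny":
        return TinyBackbone(rng=rng, **kwargs)
    raise ValueError(f"unknown backbone: {name}")
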