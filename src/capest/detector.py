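"""The assembled single-stage pest detector.

``PestDetector`` wires a multi-scale backbone, the (coordinate-attention)
feature pyramid, the anchor-free head, and the learnable class-specific
center prior used by the dynamic sample weighting.  Three named profiles
cover the package's use cases:

* :func:`default_profile` — ResNet-50 + CAFPN + 21-class head, the
  full-scale pest-detection configuration;
* :func:`reference_profile` — the configuration under which the published
  efficiency figures of this detector family are customarily computed:
  stock 80-category head, frozen stem and first backbone stage, and
  caffe-style frozen batch-norm affine transforms.  Useful for parameter
  accounting and cross-implementation comparison;
* :func:`desk_profile` — a tiny CPU-scale detector (five-conv backbone,
  narrow pyramid, 128x128 inputs) for end-to-end experiments in minutes.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .backbones import ResNet50, TinyBackbone
from .cafpn import CAFPN, FpnConfig
from .detection_head import DetectionHead, HeadOutputs, decode
from .label_weighting import ClassPrior
from .nn import Module

__all__ = ["PestDetector", "default_profile", "reference_profile",
           "desk_profile", "FULL_LEVEL_RANGES", "DESK_LEVEL_RANGES"]

# object-size routing ranges (pixels, by longest box side) per pyramid level
FULL_LEVEL_RANGES = ((0, 64), (64, 128), (128, 256), (256, 512), (512, 1e9))
DESK_LEVEL_RANGES = ((0, 24), (24, 48), (48, 1e9))


class PestDetector(Module):
    def __init__(self, backbone, fpn: CAFPN, head: DetectionHead,
                 prior: ClassPrior, level_ranges):
        self.backbone = backbone
        self.fpn = fpn
        self.head = head
        self.prior = prior
        self.level_ranges = tuple(level_ranges)

    @property
    def num_classes(self) -> int:
        return self.head.num_classes

    def forward(self, images: Tensor) -> HeadOutputs:
        return self.head(self.fpn(self.backbone(images)))

    def predict(self, image: np.ndarray, score_thresh: float = 0.05,
                nms_iou: float = 0.6, max_dets: int = 100):
        """Run one uint8 HWC image through the detector."""
        x = prepare_image(image)
        outputs = self.forward(Tensor(x[None]))
        return decode(outputs, score_thresh=score_thresh, nms_iou=nms_iou,
                      max_dets=max_dets,
                      image_size=(image.shape[1], image.shape[0]))


def prepare_image(image: np.ndarray) -> np.ndarray:
    """uint8 HWC -> float32 CHW, zero-centered."""
    x = np.asarray(image, dtype=np.float32) / 255.0
    return ((x - 0.5) / 0.25).transpose(2, 0, 1)


def default_profile(num_classes: int = 21, use_ca: bool = True,
                    seed: int = 0) -> PestDetector:
    """Full-scale configuration: ResNet-50, CAFPN(256), five levels."""
    rng = np.random.default_rng(seed)
    backbone = ResNet50(frozen_stages=1, norm_trainable=False, rng=rng)
    fpn = CAFPN(backbone.out_channels,
                FpnConfig(width=256, use_ca=use_ca, extra_levels=2), rng=rng)
    head = DetectionHead(num_classes, in_channels=256, num_levels=5,
                         strides=(8, 16, 32, 64, 128), tower_convs=4,
                         use_gn=True, rng=rng)
    return PestDetector(backbone, fpn, head, ClassPrior(num_classes),
                        FULL_LEVEL_RANGES)


def reference_profile(use_ca: bool = True, seed: int = 0) -> PestDetector:
    """Stock 80-category configuration used for parameter accounting."""
    return default_profile(num_classes=80, use_ca=use_ca, seed=seed)


def desk_profile(num_classes: int = 4, use_ca: bool = True,
                 width: int = 32, tower_convs: int = 1,
                 seed: int = 0) -> PestDetector:
    """CPU-scale configuration for 128x128 synthetic scenes."""
    rng = np.random.default_rng(seed)
    backbone = TinyBackbone(rng=rng)
    fpn = CAFPN(backbone.out_channels,
                FpnConfig(width=width, use_ca=use_ca, ca_reduction=2.0,
                          extra_levels=0), rng=rng)
    head = DetectionHead(num_classes, in_channels=width, num_levels=3,
                         strides=(8, 16, 32), tower_convs=tower_convs,
                         use_gn=True, rng=rng)
    return PestDetector(backbone, fpn, head, ClassPrior(num_classes),
                        DESK_LEVEL_RANGES)
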