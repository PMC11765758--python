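"""Anchor-free multi-class detection head.

At every feature-grid point the head predicts (i) per-class scores, (ii)
four nonnegative distances (left, top, right, bottom, in image pixels) from
the point to the box boundary, and (iii) a centerness score estimating how
central the point sits within its object.  The classification branch has
its own convolution tower; the regression and centerness branches share a
second tower.  Tower weights are shared across pyramid levels; distances
are made positive through an exponential with a per-level learnable scale,
multiplied by the level stride.

Decoding turns the per-level maps into scored boxes:

    box = (x - l, y - t, x + r, y + b),  score = sqrt(p_cls * p_ctr)

followed by class-wise non-maximum suppression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .errors import ConfigurationError
from .nn import Conv2d, GroupNorm, Module, ReLU, Scale, Sequential

__all__ = ["HeadOutputs", "Detection", "GTObject", "DetectionHead",
           "grid_points", "decode", "nms", "box_iou_matrix"]


@dataclass
class Detection:
    """A predicted box (x1, y1, x2, y2), 0-based pixels, x2/y2 exclusive."""

    box: tuple
    label: int
    score: float


@dataclass
class GTObject:
    """A ground-truth box with its class index."""

    box: tuple
    label: int

    @property
    def area(self) -> float:
        x1, y1, x2, y2 = self.box
        return max(0.0, x2 - x1) * max(0.0, y2 - y1)


@dataclass
class HeadOutputs:
    """Per-level raw head outputs plus the lattice geometry.

    ``cls_logits[i]``: (N, C, Hi, Wi) pre-sigmoid class scores;
    ``distances[i]``: (N, 4, Hi, Wi) nonnegative l/t/r/b in pixels;
    ``ctr_logits[i]``: (N, 1, Hi, Wi) pre-sigmoid centerness;
    ``points[i]``: (Hi*Wi, 2) image-plane (x, y) of each cell, row-major.
    """

    cls_logits: list
    distances: list
    ctr_logits: list
    points: list
    strides: tuple


def grid_points(level_shape, stride: float) -> np.ndarray:
    """Image coordinates of cell centers: (stride/2 + stride*col, ... row)."""
    if stride <= 0:
        raise ValueError("stride must be positive")
    h, w = level_shape
    xs = stride / 2.0 + stride * np.arange(w)
    ys = stride / 2.0 + stride * np.arange(h)
    gx, gy = np.meshgrid(xs, ys)
    return np.stack([gx.ravel(), gy.ravel()], axis=1).astype(np.float32)


def _tower(n_convs, in_ch, ch, use_gn, rng):
    layers = []
    for i in range(n_convs):
        layers.append(Conv2d(in_ch if i == 0 else ch, ch, 3, padding=1,
                             bias=not use_gn, rng=rng, init_std=0.01))
        if use_gn:
            layers.append(GroupNorm(32 if ch % 32 == 0 else min(8, ch), ch))
        layers.append(ReLU())
    return Sequential(*layers)


class DetectionHead(Module):
    """Shared-weight three-branch head over all pyramid levels."""

    def __init__(self, num_classes: int, in_channels: int = 256,
                 num_levels: int = 5, strides=(8, 16, 32, 64, 128),
                 tower_convs: int = 4, use_gn: bool = True,
                 prior_prob: float = 0.01,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        if len(strides) != num_levels:
            raise ConfigurationError("one stride per level required")
        self.num_classes = num_classes
        self.in_channels = in_channels
        self.strides = tuple(strides)
        self.cls_tower = _tower(tower_convs, in_channels, in_channels, use_gn, rng)
        self.reg_tower = _tower(tower_convs, in_channels, in_channels, use_gn, rng)
        self.cls_conv = Conv2d(in_channels, num_classes, 3, padding=1,
                               rng=rng, init_std=0.01)
        # rare-positive bias prior keeps early training stable
        self.cls_conv.bias.data[:] = -math.log((1 - prior_prob) / prior_prob)
        self.reg_conv = Conv2d(in_channels, 4, 3, padding=1, rng=rng, init_std=0.01)
        self.ctr_conv = Conv2d(in_channels, 1, 3, padding=1, rng=rng, init_std=0.01)
        self.scales = [Scale(1.0) for _ in range(num_levels)]

    def forward(self, pyramid) -> HeadOutputs:
        if pyramid[0].shape[1] != self.in_channels:
            raise ConfigurationError(
                f"pyramid width {pyramid[0].shape[1]} != head width {self.in_channels}")
        cls_logits, distances, ctr_logits, points = [], [], [], []
        for level, feat in enumerate(pyramid):
            stride = self.strides[level]
            ct = self.cls_tower(feat)
            rt = self.reg_tower(feat)
            cls_logits.append(self.cls_conv(ct))
            ctr_logits.append(self.ctr_conv(rt))
            raw = self.scales[level](self.reg_conv(rt))
            distances.append(raw.exp() * float(stride))
            points.append(grid_points(feat.shape[2:], stride))
        return HeadOutputs(cls_logits, distances, ctr_logits, points,
                           self.strides[:len(pyramid)])


# -- decoding ------------------------------------------------------------------

def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two (n,4) / (m,4) box arrays."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    order = np.argsort(-scores, kind="stable")
    boxes = np.asarray(boxes, dtype=np.float64)
    keep = []
    alive = np.ones(len(order), dtype=bool)
    for oi, i in enumerate(order):
        if not alive[oi]:
            continue
        keep.append(int(i))
        rest = order[oi + 1:][alive[oi + 1:]]
        if len(rest) == 0:
            break
        ious = box_iou_matrix(boxes[i][None], boxes[rest])[0]
        dead = rest[ious > iou_thr]
        if len(dead):
            mask = np.isin(order, dead)
            alive[mask] = False
    return np.array(keep, dtype=int)


def decode(outputs: HeadOutputs, score_thresh: float = 0.05,
           nms_iou: float = 0.6, max_dets: int = 100,
           image_size: tuple | None = None, batch_index: int = 0):
    """Turn head outputs into a list of :class:`Detection` for one image."""
    if not (0 <= score_thresh <= 1 and 0 <= nms_iou <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    all_boxes, all_scores, all_labels = [], [], []
    for cls_l, dist_l, ctr_l, pts in zip(outputs.cls_logits, outputs.distances,
                                         outputs.ctr_logits, outputs.points):
        cls = cls_l.data[batch_index]          # (C, H, W)
        dist = dist_l.data[batch_index]        # (4, H, W)
        ctr = ctr_l.data[batch_index]          # (1, H, W)
        c = cls.shape[0]
        p_cls = 1.0 / (1.0 + np.exp(-cls.reshape(c, -1)))      # (C, M)
        p_ctr = 1.0 / (1.0 + np.exp(-ctr.reshape(1, -1)))      # (1, M)
        score = np.sqrt(p_cls * p_ctr)                          # (C, M)
        d = dist.reshape(4, -1)
        boxes = np.stack([pts[:, 0] - d[0], pts[:, 1] - d[1],
                          pts[:, 0] + d[2], pts[:, 1] + d[3]], axis=1)
        if image_size is not None:
            w, h = image_size
            boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, w)
            boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, h)
        ci, mi = np.nonzero(score > score_thresh)
        all_boxes.append(boxes[mi])
        all_scores.append(score[ci, mi])
        all_labels.append(ci)
    boxes = np.concatenate(all_boxes) if all_boxes else np.zeros((0, 4))
    scores = np.concatenate(all_scores) if all_scores else np.zeros(0)
    labels = np.concatenate(all_labels) if all_labels else np.zeros(0, dtype=int)

    detections = []
    for c in np.unique(labels):
        sel = labels == c
        keep = nms(boxes[sel], scores[sel], nms_iou)
        for i in keep:
            b = boxes[sel][i]
            if b[2] > b[0] and b[3] > b[1]:
                detections.append(Detection(tuple(float(v) for v in b),
                                            int(c), float(scores[sel][i])))
    detections.sort(key=lambda d: -d.score)
    return detections[:max_dets]
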