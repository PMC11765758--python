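"""Soft-weighted detection losses.

Classification uses weighted log terms per (location, class):

    L_cls = -w+ * ln(p) - w- * ln(1 - p)

summed over locations and classes and normalized by the number of
positive-weighted samples.  Regression applies the positive weights to a
GIoU loss between decoded and ground-truth boxes; the centerness branch is
trained with binary cross-entropy against the usual geometric target
``sqrt((min(l,r)/max(l,r)) * (min(t,b)/max(t,b)))`` at positive samples.

Gradients flow into the Gaussian prior (mu, theta) through the positive
weights of the classification term only; the negative weights and the
regression copy of ``w+`` are treated as constants (a configuration
switch flips this).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .detection_head import HeadOutputs, box_iou_matrix
from .label_weighting import (ClassPrior, build_candidate_sets,
                              negative_weights, positive_weights)

__all__ = ["LossBreakdown", "soft_cls_loss", "soft_reg_loss",
           "centerness_loss", "giou_loss", "detection_loss"]

_EPS = 1e-6


@dataclass
class LossBreakdown:
    cls_loss: float
    reg_loss: float
    ctr_loss: float
    total_tensor: Tensor | None = None

    @property
    def total(self) -> float:
        return self.cls_loss + self.reg_loss + self.ctr_loss


def soft_cls_loss(p: Tensor, w_pos_entries, w_neg: np.ndarray,
                  normalizer: float | None = None) -> Tensor:
    """Weighted binary log loss over a (M, C) probability matrix.

    ``w_pos_entries``: triples ``(sample_idx, class_idx, weights)`` where
    ``weights`` is a Tensor (gradients flow into the prior through it);
    ``w_neg``: (M,) or (M, C) constant negative weights (a flat vector is
    broadcast over classes).
    """
    p = p.clip(_EPS, 1.0 - _EPS)
    w_neg = np.asarray(w_neg, dtype=p.dtype)
    if w_neg.ndim == 1:
        w_neg = w_neg[:, None]
    loss = -((1.0 - p).log() * Tensor(w_neg)).sum()
    n_pos_samples = 0
    for sample_idx, class_idx, w in w_pos_entries:
        if len(sample_idx) == 0:
            continue
        n_pos_samples += len(sample_idx)
        picked = p[np.asarray(sample_idx), np.asarray(class_idx)]
        loss = loss - (w * picked.log()).sum()
    norm = normalizer if normalizer is not None else max(n_pos_samples, 1)
    return loss * (1.0 / float(norm))


def giou_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Per-box ``1 - GIoU``; in [0, 2], 0 iff boxes coincide."""
    t = np.asarray(target, dtype=np.float64).reshape(-1, 4).astype(pred.dtype)
    px1, py1, px2, py2 = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    tx1, ty1, tx2, ty2 = (Tensor(t[:, i]) for i in range(4))
    iw = ad.maximum(ad.minimum(px2, tx2) - ad.maximum(px1, tx1), 0.0)
    ih = ad.maximum(ad.minimum(py2, ty2) - ad.maximum(py1, ty1), 0.0)
    inter = iw * ih
    area_p = ad.maximum(px2 - px1, 0.0) * ad.maximum(py2 - py1, 0.0)
    area_t = (tx2 - tx1) * (ty2 - ty1)
    union = area_p + area_t - inter
    iou = inter / (union + _EPS)
    # smallest enclosing box
    ew = ad.maximum(px2, tx2) - ad.minimum(px1, tx1)
    eh = ad.maximum(py2, ty2) - ad.minimum(py1, ty1)
    enclose = ew * eh + _EPS
    giou = iou - (enclose - union) / enclose
    return 1.0 - giou


def iou_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Plain ``-ln(IoU)``-free variant: ``1 - IoU`` (selectable alternative)."""
    t = np.asarray(target, dtype=np.float64).reshape(-1, 4).astype(pred.dtype)
    px1, py1, px2, py2 = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    tx1, ty1, tx2, ty2 = (Tensor(t[:, i]) for i in range(4))
    iw = ad.maximum(ad.minimum(px2, tx2) - ad.maximum(px1, tx1), 0.0)
    ih = ad.maximum(ad.minimum(py2, ty2) - ad.maximum(py1, ty1), 0.0)
    inter = iw * ih
    area_p = ad.maximum(px2 - px1, 0.0) * ad.maximum(py2 - py1, 0.0)
    area_t = (tx2 - tx1) * (ty2 - ty1)
    union = area_p + area_t - inter
    return 1.0 - inter / (union + _EPS)


def soft_reg_loss(pred_boxes: Tensor, gt_boxes: np.ndarray, w_pos: np.ndarray,
                  normalizer: float | None = None,
                  kind: str = "giou") -> Tensor:
    """``sum_i w+_i * l_reg(b_i, b*_i)``, positives only.

    Degenerate (non-positive-area) ground-truth boxes are excluded.
    """
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    w_pos = np.asarray(w_pos, dtype=np.float64)
    ok = (gt_boxes[:, 2] > gt_boxes[:, 0]) & (gt_boxes[:, 3] > gt_boxes[:, 1])
    if not ok.all():
        warnings.warn("degenerate ground-truth boxes excluded from regression")
        sel = np.nonzero(ok)[0]
        pred_boxes, gt_boxes, w_pos = pred_boxes[sel], gt_boxes[sel], w_pos[sel]
    if len(gt_boxes) == 0:
        return Tensor(np.zeros((), dtype=np.float32))
    per_box = giou_loss(pred_boxes, gt_boxes) if kind == "giou" else \
        iou_loss(pred_boxes, gt_boxes)
    total = (per_box * Tensor(w_pos.astype(per_box.dtype))).sum()
    if normalizer:
        total = total * (1.0 / float(normalizer))
    return total


def centerness_targets(dists: np.ndarray) -> np.ndarray:
    """``sqrt((min(l,r)/max(l,r)) * (min(t,b)/max(t,b)))`` from (k,4) l/t/r/b."""
    d = np.asarray(dists, dtype=np.float64).reshape(-1, 4)
    lr = d[:, [0, 2]]
    tb = d[:, [1, 3]]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (lr.min(1) / np.maximum(lr.max(1), _EPS)) * \
            (tb.min(1) / np.maximum(tb.max(1), _EPS))
    return np.sqrt(np.clip(t, 0.0, 1.0))


def centerness_loss(logits: Tensor, targets: np.ndarray,
                    normalizer: float | None = None) -> Tensor:
    """Binary cross-entropy on the centerness branch at positive samples."""
    targets = np.asarray(targets, dtype=np.float64)
    if len(targets) == 0:
        return Tensor(np.zeros((), dtype=np.float32))
    if targets.min() < 0 or targets.max() > 1:
        raise ValueError("centerness targets must lie in [0, 1]")
    p = logits.sigmoid().clip(_EPS, 1.0 - _EPS)
    t = Tensor(targets.astype(p.dtype))
    loss = -(t * p.log() + (1.0 - t) * (1.0 - p).log()).sum()
    norm = normalizer if normalizer is not None else max(len(targets), 1)
    return loss * (1.0 / float(norm))


# -- full training loss --------------------------------------------------------

def _flatten_outputs(outputs: HeadOutputs, batch_index: int):
    """Concatenate per-level maps of one image into flat (M, ...) tensors."""
    cls, dist, ctr, pts = [], [], [], []
    for cl, dl, tl, p in zip(outputs.cls_logits, outputs.distances,
                             outputs.ctr_logits, outputs.points):
        c = cl.shape[1]
        cls.append(cl[batch_index].reshape(c, -1).transpose(1, 0))
        dist.append(dl[batch_index].reshape(4, -1).transpose(1, 0))
        ctr.append(tl[batch_index].reshape(-1))
        pts.append(p)
    return (ad.concatenate(cls, axis=0), ad.concatenate(dist, axis=0),
            ad.concatenate(ctr, axis=0), pts, np.concatenate(pts, axis=0))


def detection_loss(outputs: HeadOutputs, gts_batch, prior: ClassPrior,
                   level_ranges, strategy: str = "dynamic",
                   center_radius: float = 1.5, reg_kind: str = "giou",
                   learn_prior: bool = True) -> LossBreakdown:
    """Total loss over a batch.

    ``strategy='dynamic'`` uses the Gaussian-prior positive weights and
    IoU-driven negative weights; ``strategy='center'`` is the fixed
    center-sampling baseline (uniform weights over points within
    ``center_radius * stride`` of the box center, hard negatives).
    """
    n_images = len(gts_batch)
    cls_total = Tensor(np.zeros((), dtype=np.float32))
    reg_total = Tensor(np.zeros((), dtype=np.float32))
    ctr_total = Tensor(np.zeros((), dtype=np.float32))
    total_pos = 0

    for bi in range(n_images):
        gts = gts_batch[bi]
        cls_flat, dist_flat, ctr_flat, pts_levels, pts_all = \
            _flatten_outputs(outputs, bi)
        m = cls_flat.shape[0]
        p = cls_flat.sigmoid()

        if len(gts) == 0:
            # background-only image: every location is a weight-1 negative
            cls_total = cls_total + soft_cls_loss(p, [], np.ones(m), normalizer=1)
            continue

        sets = build_candidate_sets(gts, pts_levels, level_ranges)
        level_offsets = np.cumsum([0] + [len(q) for q in pts_levels])
        gt_boxes = np.array([g.box for g in gts], dtype=np.float64)

        # decode predicted boxes at every location (constant for weighting)
        d_np = dist_flat.data
        pred_boxes_all = np.stack(
            [pts_all[:, 0] - d_np[:, 0], pts_all[:, 1] - d_np[:, 1],
             pts_all[:, 0] + d_np[:, 2], pts_all[:, 1] + d_np[:, 3]], axis=1)

        inside_any = np.zeros(m, dtype=bool)
        for s in sets:
            inside_any[level_offsets[s.level] + s.point_indices] = True

        if strategy == "dynamic":
            w_pos_list = positive_weights(sets, prior)
            if not learn_prior:
                w_pos_list = [w.detach() for w in w_pos_list]
            k = box_iou_matrix(pred_boxes_all, gt_boxes).max(axis=1)
            w_loc = negative_weights(inside_any, k)
            # the soft negative weight relaxes only the class channel of the
            # object(s) containing a location; every other channel stays a
            # definite negative (weight 1)
            n_cls = p.shape[1]
            w_neg = np.ones((m, n_cls))
            for s in sets:
                rows = level_offsets[s.level] + s.point_indices
                w_neg[rows, s.label] = w_loc[rows]
        elif strategy == "center":
            w_pos_list, keep_sets = [], []
            for s in sets:
                stride = 8.0 * 2 ** s.level
                x1, y1, x2, y2 = gts[s.object_index].box
                half = np.array([max((x2 - x1) / 2, 1e-6),
                                 max((y2 - y1) / 2, 1e-6)])
                r = np.abs(s.displacements * half)
                near = (r[:, 0] <= center_radius * stride) & \
                       (r[:, 1] <= center_radius * stride)
                if not near.any():
                    near = np.zeros(len(s.point_indices), dtype=bool)
                    near[np.abs(s.displacements).sum(1).argmin()] = True
                s.point_indices = s.point_indices[near]
                s.displacements = s.displacements[near]
                w = np.full(near.sum(), 1.0 / near.sum(), dtype=np.float32)
                w_pos_list.append(Tensor(w))
                keep_sets.append(s)
            sets = keep_sets
            w_neg = np.ones((m, p.shape[1]))
            for s in sets:
                w_neg[level_offsets[s.level] + s.point_indices, s.label] = 0.0
        else:
            raise ValueError(f"unknown assignment strategy: {strategy}")

        entries, reg_rows, reg_targets, reg_w, ctr_rows, ctr_targets = \
            [], [], [], [], [], []
        for s, w in zip(sets, w_pos_list):
            flat_idx = level_offsets[s.level] + s.point_indices
            entries.append((flat_idx, np.full(len(flat_idx), s.label), w))
            reg_rows.append(flat_idx)
            reg_targets.append(np.repeat(gt_boxes[s.object_index][None],
                                         len(flat_idx), axis=0))
            reg_w.append(w.data if isinstance(w, Tensor) else w)
            x1, y1, x2, y2 = gts[s.object_index].box
            px, py = pts_all[flat_idx, 0], pts_all[flat_idx, 1]
            ctr_rows.append(flat_idx)
            ctr_targets.append(centerness_targets(
                np.stack([px - x1, py - y1, x2 - px, y2 - py], axis=1)))

        n_pos = int(sum(len(r) for r in reg_rows))
        total_pos += n_pos
        cls_total = cls_total + soft_cls_loss(p, entries, w_neg,
                                              normalizer=max(n_pos, 1))
        rows = np.concatenate(reg_rows)
        reg_total = reg_total + soft_reg_loss(
            dist_flat_to_boxes(dist_flat, pts_all, rows),
            np.concatenate(reg_targets, axis=0),
            np.concatenate(reg_w), normalizer=None, kind=reg_kind)
        ctr_total = ctr_total + centerness_loss(
            ctr_flat[np.concatenate(ctr_rows)],
            np.concatenate(ctr_targets), normalizer=max(n_pos, 1))

    scale = 1.0 / max(n_images, 1)
    cls_t = cls_total * scale
    reg_t = reg_total * scale
    ctr_t = ctr_total * scale
    total = cls_t + reg_t + ctr_t
    return LossBreakdown(cls_loss=float(cls_t.data), reg_loss=float(reg_t.data),
                         ctr_loss=float(ctr_t.data), total_tensor=total)


def dist_flat_to_boxes(dist_flat: Tensor, pts_all: np.ndarray,
                       rows: np.ndarray) -> Tensor:
    """Decode (l, t, r, b) rows into (x1, y1, x2, y2) boxes, differentiably."""
    d = dist_flat[rows]
    px = Tensor(pts_all[rows, 0].astype(d.dtype))
    py = Tensor(pts_all[rows, 1].astype(d.dtype))
    return ad.stack([px - d[:, 0], py - d[:, 1],
                     px + d[:, 2], py + d[:, 3]], axis=1)
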