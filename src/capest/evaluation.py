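"""COCO-protocol detection metrics and model-size accounting.

Average precision follows the standard COCO evaluation: per-class
precision-recall curves with 101-point interpolation, IoU thresholds 0.5
to 0.95 in steps of 0.05, greedy score-ordered matching, and size strata
at areas 32^2 and 96^2 (small < 32^2 <= medium < 96^2 <= large).  Average
recall is reported at up to 100 detections per image.  Ground truth
outside the active area stratum is ignored; detections matched to ignored
ground truth, or unmatched detections falling outside the stratum, do not
count as false positives (the pycocotools semantics).

Metrics are returned in [0, 1]; multiply by 100 for the conventional
percentage form.  A stratum with no ground truth reports the sentinel -1.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .detection_head import box_iou_matrix

__all__ = ["EvalReport", "evaluate", "count_parameters", "detections_to_coco"]

IOU_THRESHOLDS = np.round(np.arange(0.5, 1.0, 0.05), 2)
RECALL_POINTS = np.linspace(0.0, 1.0, 101)
AREA_RANGES = {
    "all": (0.0, float("inf")),
    "small": (0.0, 32.0 ** 2),
    "medium": (32.0 ** 2, 96.0 ** 2),
    "large": (96.0 ** 2, float("inf")),
}


@dataclass
class EvalReport:
    ap: float          # AP averaged over IoU 0.5:0.05:0.95
    ap50: float
    ap75: float
    ap_small: float
    ap_medium: float
    ap_large: float
    ar_small: float
    ar_medium: float
    ar_large: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def summary(self) -> str:
        return "\n".join(f"{k:>10s}: {100 * v:6.1f}%" if v >= 0 else
                         f"{k:>10s}:    n/a" for k, v in self.as_dict().items())


def _box_area(box) -> float:
    return max(0.0, box[2] - box[0]) * max(0.0, box[3] - box[1])


def _match_image(iou: np.ndarray, order: np.ndarray, gt_ignore: np.ndarray,
                 iou_thr: float) -> np.ndarray:
    """Greedy score-ordered matching for one image/class/threshold.

    Each detection (in score order) takes the still-free ground-truth box
    of highest IoU >= threshold, preferring real boxes over ignored ones.
    Returns the matched GT index per detection (-1 if unmatched).
    """
    matches = np.full(iou.shape[0], -1, dtype=int)
    taken = np.zeros(iou.shape[1], dtype=bool)
    for di in order:
        best, best_iou = -1, iou_thr - 1e-12
        for gi in range(iou.shape[1]):
            if taken[gi] and not gt_ignore[gi]:
                continue
            if best >= 0 and not gt_ignore[best] and gt_ignore[gi]:
                continue  # never trade a real match for an ignored one
            if iou[di, gi] > best_iou or \
                    (best >= 0 and gt_ignore[best] and not gt_ignore[gi]
                     and iou[di, gi] >= iou_thr):
                best, best_iou = gi, iou[di, gi]
        if best >= 0:
            matches[di] = best
            taken[best] = True
    return matches


def _pr_ap(rows, n_gt: int) -> float:
    """101-point interpolated AP from (score, is_tp) rows."""
    rows = sorted(rows, key=lambda r: -r[0])
    tp = np.cumsum([t for _, t in rows])
    fp = np.cumsum([1 - t for _, t in rows])
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    for i in range(len(precision) - 2, -1, -1):
        precision[i] = max(precision[i], precision[i + 1])
    ap = 0.0
    for rp in RECALL_POINTS:
        idx = np.searchsorted(recall, rp, side="left")
        ap += precision[idx] if idx < len(precision) else 0.0
    return ap / len(RECALL_POINTS)


def evaluate(detections: dict, ground_truth: dict,
             max_dets: int = 100) -> EvalReport:
    """Compute the report from per-image detection and ground-truth dicts.

    Both arguments map ``image_id -> list``; ground-truth entries carry
    ``.box`` and ``.label`` (:class:`~capest.detection_head.GTObject`),
    detection entries carry ``.box``, ``.label`` and ``.score``.
    """
    image_ids = sorted(set(ground_truth) | set(detections))
    labels = sorted({g.label for gts in ground_truth.values() for g in gts})
    if not labels:
        return EvalReport(*([-1.0] * 9))

    ap_tables = {name: [] for name in AREA_RANGES}
    ar_tables = {name: [] for name in AREA_RANGES}
    n_thr = len(IOU_THRESHOLDS)

    for area_name, (amin, amax) in AREA_RANGES.items():
        for cls in labels:
            rows = [[] for _ in range(n_thr)]     # (score, tp) per threshold
            matched = np.zeros(n_thr)
            n_gt = 0
            for img in image_ids:
                gts = [g for g in ground_truth.get(img, []) if g.label == cls]
                dts = sorted((d for d in detections.get(img, [])
                              if d.label == cls), key=lambda d: -d.score)[:max_dets]
                gt_boxes = np.array([g.box for g in gts]).reshape(-1, 4)
                gt_ign = np.array([not (amin <= _box_area(g.box) < amax)
                                   for g in gts], dtype=bool)
                n_gt += int((~gt_ign).sum())
                if not dts:
                    continue
                dt_boxes = np.array([d.box for d in dts]).reshape(-1, 4)
                iou = box_iou_matrix(dt_boxes, gt_boxes)
                order = np.arange(len(dts))        # already score-sorted
                for ti, thr in enumerate(IOU_THRESHOLDS):
                    matches = _match_image(iou, order, gt_ign, thr)
                    for di, d in enumerate(dts):
                        mi = matches[di]
                        if mi >= 0 and gt_ign[mi]:
                            continue               # matched an ignored GT
                        if mi < 0 and not (amin <= _box_area(d.box) < amax):
                            continue               # off-stratum false positive
                        rows[ti].append((d.score, 1 if mi >= 0 else 0))
                    matched[ti] += sum(1 for mi in matches
                                       if mi >= 0 and not gt_ign[mi])
            if n_gt == 0:
                continue
            ap_tables[area_name].append(
                np.array([_pr_ap(rows[ti], n_gt) for ti in range(n_thr)]))
            ar_tables[area_name].append(matched / n_gt)

    def mean_ap(area, thr_index=None):
        table = ap_tables[area]
        if not table:
            return -1.0
        arr = np.stack(table)
        return float(arr.mean() if thr_index is None else arr[:, thr_index].mean())

    def mean_ar(area):
        table = ar_tables[area]
        return float(np.stack(table).mean()) if table else -1.0

    t50 = int(np.argwhere(IOU_THRESHOLDS == 0.5)[0, 0])
    t75 = int(np.argwhere(IOU_THRESHOLDS == 0.75)[0, 0])
    return EvalReport(
        ap=mean_ap("all"), ap50=mean_ap("all", t50), ap75=mean_ap("all", t75),
        ap_small=mean_ap("small"), ap_medium=mean_ap("medium"),
        ap_large=mean_ap("large"),
        ar_small=mean_ar("small"), ar_medium=mean_ar("medium"),
        ar_large=mean_ar("large"),
    )


def count_parameters(model, trainable_only: bool = True) -> float:
    """Trainable scalar parameters in millions (two-decimal convention)."""
    return model.num_parameters(trainable_only=trainable_only) / 1e6


def detections_to_coco(detections: dict) -> list:
    """Export per-image detections as COCO results records."""
    out = []
    for image_id, dts in detections.items():
        for d in dts:
            x1, y1, x2, y2 = d.box
            out.append({"image_id": image_id, "category_id": d.label + 1,
                        "bbox": [x1, y1, x2 - x1, y2 - y1],
                        "score": d.score})
    return out
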