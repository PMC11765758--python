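"""Dynamic soft positive/negative sample weighting.

Instead of a hard positive/negative split, every grid point inside a
ground-truth box receives a *soft* positive weight from a learnable,
category-specific Gaussian center prior, and a *soft* negative weight
driven by the IoU of its predicted box with the ground truth:

* positive weights:  ``w+_i = G(d_i) / sum_j G(d_j)`` over the candidate
  set of each object, where ``G(d | mu, theta) = exp(-sum_a (d_a -
  mu_a)^2 / theta_a^2)`` and ``d`` is the displacement from the point to
  the box center, normalized by the half extent of the box per axis.
  ``mu`` (per-class center offset) and ``theta`` (per-class spread) are
  learnable of shape (C, 2); ``theta`` controls how many point samples
  effectively contribute.
* negative weights:  ``w-_i = 1 - N(1 / (1 - k_i))`` where ``k_i`` is the
  maximum IoU between the point's predicted box and any ground-truth box
  and ``N`` max-normalizes, so the best-IoU in-box sample incurs no
  negative penalty; every point outside all boxes keeps ``w- = 1``.

Candidate sets are built per object: each object is routed to one pyramid
level by its box size (standard level-range partitioning) and its
candidates are that level's grid points falling inside the box; an object
whose box contains no grid point falls back to the single nearest point of
its level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .detection_head import box_iou_matrix
from .errors import ValidationError
from .nn import Module, Parameter

__all__ = ["ClassPrior", "CandidateSet", "SampleWeights", "gaussian_prior",
           "positive_weights", "box_iou", "negative_weights",
           "build_candidate_sets", "assign_levels"]


class ClassPrior(Module):
    """Learnable per-class Gaussian center prior.

    ``mu`` is stored directly (init 0: centered prior); ``theta`` is stored
    through a log-parameterization ``theta = exp(rho)`` (init ``rho = 0``,
    i.e. unit spread) so positivity holds for any parameter value.
    """

    def __init__(self, num_classes: int, mu_lr_mult: float = 3.0):
        self.num_classes = num_classes
        # mu's gradients are averages of per-object normalized weights and
        # run an order of magnitude smaller than conv gradients; a larger
        # step keeps the center offset responsive.  theta keeps the base
        # rate: large steps on the log-spread destabilize the weights.
        self.mu = Parameter(np.zeros((num_classes, 2), dtype=np.float32),
                            lr_mult=mu_lr_mult)
        self.rho = Parameter(np.zeros((num_classes, 2), dtype=np.float32))

    @property
    def theta(self) -> Tensor:
        return self.rho.exp()

    def theta_values(self) -> np.ndarray:
        return np.exp(self.rho.data)


@dataclass
class CandidateSet:
    """Candidate point samples of one ground-truth object."""

    object_index: int
    label: int
    level: int
    point_indices: np.ndarray      # indices into the flat per-level lattice
    displacements: np.ndarray      # (k, 2) normalized (center - point)/half


@dataclass
class SampleWeights:
    """Per-object positive weights and per-location negative weights."""

    w_pos: list                    # one Tensor (k,) per object; each sums to 1
    w_neg: np.ndarray              # (M,) in [0, 1]; 1 outside every GT box


def gaussian_prior(d, labels, prior: ClassPrior) -> Tensor:
    """``G(d | mu_c, theta_c) = exp(-sum_axis (d_a - mu_a)^2 / theta_a^2)``.

    Differentiable in ``mu`` and ``theta``; maximal value 1 at ``d = mu``.
    ``d``: (k, 2) displacements; ``labels``: (k,) class index per row.
    """
    d = np.asarray(d, dtype=np.float32).reshape(-1, 2)
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    if labels.size == 1 and d.shape[0] > 1:
        labels = np.full(d.shape[0], labels[0])
    if np.any(prior.theta_values() <= 0):
        raise ValidationError("theta must be strictly positive")
    mu = prior.mu[labels]                 # (k, 2), gathers keep the gradient
    theta = prior.rho[labels].exp()
    z = (Tensor(d) - mu) / theta
    return (-(z * z).sum(axis=1)).exp()


def positive_weights(sets: "list[CandidateSet] | CandidateSet",
                     prior: ClassPrior) -> list:
    """Per-object normalized positive weights: ``w+_i = G(d_i)/sum_j G(d_j)``."""
    single = isinstance(sets, CandidateSet)
    out = []
    for s in ([sets] if single else sets):
        if len(s.point_indices) == 0:
            raise ValidationError("candidate set is empty")
        g = gaussian_prior(s.displacements, s.label, prior)
        out.append(g / g.sum())
    return out[0] if single else out


def box_iou(a, b) -> float:
    """IoU of two boxes (x1, y1, x2, y2); zero-area boxes give 0."""
    return float(box_iou_matrix(np.asarray(a), np.asarray(b))[0, 0])


def negative_weights(inside_any: np.ndarray, k: np.ndarray,
                     sharpen: float = 1.0, eps: float = 1e-6) -> np.ndarray:
    """IoU-driven negative weights for every location.

    ``inside_any``: (M,) bool, whether the location lies inside some GT box;
    ``k``: (M,) max IoU of the location's predicted box with all GT boxes.
    In-box locations get ``1 - (t_i / t_max)^sharpen`` with
    ``t_i = 1/(1 - k_i)``; the max-IoU in-box location gets exactly 0 and
    out-of-box locations get exactly 1.
    """
    inside_any = np.asarray(inside_any, dtype=bool)
    k = np.clip(np.asarray(k, dtype=np.float64), 0.0, 1.0 - eps)
    w = np.ones(len(k), dtype=np.float64)
    if inside_any.any():
        t = 1.0 / (1.0 - k[inside_any])
        w[inside_any] = 1.0 - (t / t.max()) ** sharpen
    return w


def assign_levels(boxes: np.ndarray, level_ranges) -> np.ndarray:
    """Route each object to a pyramid level by its longest box side."""
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    size = np.maximum(boxes[:, 2] - boxes[:, 0], boxes[:, 3] - boxes[:, 1])
    levels = np.zeros(len(boxes), dtype=int)
    for li, (lo, hi) in enumerate(level_ranges):
        levels[(size >= lo) & (size < hi)] = li
    return levels


def build_candidate_sets(gts, points_per_level, level_ranges):
    """Construct the candidate set of every ground-truth object.

    ``gts``: list of objects with ``.box`` and ``.label``;
    ``points_per_level``: list of (Mi, 2) lattices in image coordinates.
    """
    if len(points_per_level) != len(level_ranges):
        raise ValidationError("one size range per pyramid level required")
    boxes = np.array([g.box for g in gts], dtype=np.float64).reshape(-1, 4)
    levels = assign_levels(boxes, level_ranges)
    sets = []
    for n, g in enumerate(gts):
        li = levels[n]
        pts = points_per_level[li]
        x1, y1, x2, y2 = boxes[n]
        inside = ((pts[:, 0] > x1) & (pts[:, 0] < x2) &
                  (pts[:, 1] > y1) & (pts[:, 1] < y2))
        idx = np.nonzero(inside)[0]
        cx, cy = (x1 + x2) / 2.0, (y1 + y2) / 2.0
        if len(idx) == 0:
            # tiny box between lattice points: adopt the nearest point
            d2 = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2
            idx = np.array([int(d2.argmin())])
        half_w = max((x2 - x1) / 2.0, 1e-6)
        half_h = max((y2 - y1) / 2.0, 1e-6)
        disp = np.stack([(cx - pts[idx, 0]) / half_w,
                         (cy - pts[idx, 1]) / half_h], axis=1)
        disp = np.clip(disp, -1.0, 1.0)  # fallback point may sit outside
        sets.append(CandidateSet(object_index=n, label=int(g.label), level=int(li),
                                 point_indices=idx,
                                 displacements=disp.astype(np.float32)))
    return sets
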