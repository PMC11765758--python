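"""Head outputs, the point lattice, decoding, and NMS."""

import numpy as np
import pytest

from capest.autodiff import Tensor
from capest.detection_head import (Detection, DetectionHead, HeadOutputs,
                                   decode, grid_points, nms, box_iou_matrix)
from capest.errors import ConfigurationError


def brute_force_nms(boxes, scores, iou_thr):
    """Quadratic reference suppression: keep a box iff no higher-scored kept
    box overlaps it above the threshold."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    kept = []
    for i in order:
        ok = True
        for j in kept:
            if box_iou_matrix(boxes[i][None], boxes[j][None])[0, 0] > iou_thr:
                ok = False
                break
        if ok:
            kept.append(int(i))
    return kept


def make_outputs(points_boxes, num_classes=2, stride=8, grid=(4, 4)):
    """Construct synthetic single-level head outputs with chosen logits."""
    h, w = grid
    cls = np.full((1, num_classes, h, w), -20.0)
    dist = np.full((1, 4, h, w), 1.0)
    ctr = np.full((1, 1, h, w), 20.0)
    for (row, col, label, logit, d) in points_boxes:
        cls[0, label, row, col] = logit
        dist[0, :, row, col] = d
    return HeadOutputs(cls_logits=[Tensor(cls)],
                       distances=[Tensor(dist)],
                       ctr_logits=[Tensor(ctr)],
                       points=[grid_points(grid, stride)],
                       strides=(stride,))


class TestGridPoints:
    def test_two_by_two_stride_eight(self):
        pts = grid_points((2, 2), 8)
        np.testing.assert_array_equal(pts, [[4, 4], [12, 4], [4, 12], [12, 12]])

    def test_single_cell_large_stride(self):
        np.testing.assert_array_equal(grid_points((1, 1), 128), [[64, 64]])

    @pytest.mark.parametrize("shape", [(1, 7), (5, 3), (10, 10)])
    def test_count_equals_cells(self, shape):
        assert len(grid_points(shape, 16)) == shape[0] * shape[1]


class TestHeadForward:
    def test_output_shape_contract(self, rng):
        head = DetectionHead(num_classes=21, in_channels=16, num_levels=1,
                             strides=(32,), tower_convs=1, rng=rng)
        out = head([Tensor(rng.normal(size=(1, 16, 25, 19)).astype(np.float32))])
        assert out.cls_logits[0].shape == (1, 21, 25, 19)
        assert out.distances[0].shape == (1, 4, 25, 19)
        assert out.ctr_logits[0].shape == (1, 1, 25, 19)

    def test_distances_are_positive(self, rng):
        head = DetectionHead(num_classes=3, in_channels=8, num_levels=2,
                             strides=(8, 16), tower_convs=1, rng=rng)
        out = head([Tensor(rng.normal(size=(1, 8, 4, 4)).astype(np.float32)),
                    Tensor(rng.normal(size=(1, 8, 2, 2)).astype(np.float32))])
        assert all(np.all(d.data > 0) for d in out.distances)

    def test_bias_prior_sets_initial_probability(self, rng):
        head = DetectionHead(num_classes=5, in_channels=8, num_levels=1,
                             strides=(8,), tower_convs=1, prior_prob=0.01,
                             rng=rng)
        head.cls_conv.weight.data[:] = 0.0
        out = head([Tensor(np.zeros((1, 8, 3, 3), dtype=np.float32))])
        p = 1 / (1 + np.exp(-out.cls_logits[0].data))
        np.testing.assert_allclose(p, 0.01, rtol=1e-5)

    def test_towers_shared_across_levels(self, rng):
        head = DetectionHead(num_classes=3, in_channels=8, num_levels=2,
                             strides=(8, 16), tower_convs=2, rng=rng)
        x = rng.normal(size=(1, 8, 4, 4)).astype(np.float32)
        out = head([Tensor(x), Tensor(x)])
        np.testing.assert_array_equal(out.cls_logits[0].data,
                                      out.cls_logits[1].data)
        # with equal per-level scales, distances differ only by the stride
        np.testing.assert_allclose(out.distances[1].data,
                                   out.distances[0].data / 8.0 * 16.0,
                                   rtol=1e-5)

    def test_width_mismatch_raises(self, rng):
        head = DetectionHead(num_classes=3, in_channels=8, num_levels=1,
                             strides=(8,), tower_convs=1, rng=rng)
        with pytest.raises(ConfigurationError):
            head([Tensor(np.zeros((1, 16, 4, 4), dtype=np.float32))])


class TestDecode:
    def test_point_distance_arithmetic(self):
        out = make_outputs([(0, 0, 0, 20.0, (4.0, 4.0, 4.0, 4.0))],
                           grid=(2, 2))
        dets = decode(out, score_thresh=0.5)
        assert len(dets) == 1
        np.testing.assert_allclose(dets[0].box, (0.0, 0.0, 8.0, 8.0))
        # point (4,4) with distances 4 -> box (0,0,8,8)

    def test_boxes_contain_their_points(self, rng):
        cls = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        dist = np.abs(rng.normal(size=(1, 4, 4, 4))).astype(np.float32) + 0.1
        ctr = rng.normal(size=(1, 1, 4, 4)).astype(np.float32)
        out = HeadOutputs([Tensor(cls)], [Tensor(dist)], [Tensor(ctr)],
                          [grid_points((4, 4), 8)], (8,))
        pts = out.points[0]
        for d in decode(out, score_thresh=0.0, nms_iou=1.0, max_dets=1000):
            assert any(d.box[0] <= x <= d.box[2] and d.box[1] <= y <= d.box[3]
                       for x, y in pts)

    def test_nms_keeps_higher_scored_duplicate(self):
        out = make_outputs([(0, 0, 0, 2.2, (4, 4, 4, 4)),
                            (0, 1, 0, 1.4, (12, 4, -4, 4))], grid=(2, 2))
        # second point (12,4) with distances (12,4,-4,4) is invalid (x2<x1);
        # use an exact duplicate instead
        out.distances[0].data[:, :, 0, 1] = [12, 4, -4, 4]
        dets = decode(out, score_thresh=0.1, nms_iou=0.6)
        boxes = [d for d in dets if d.label == 0]
        assert len(boxes) == 1

    def test_score_threshold_monotonicity(self, rng):
        cls = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
        dist = np.abs(rng.normal(size=(1, 4, 4, 4))).astype(np.float32) + 1.0
        ctr = rng.normal(size=(1, 1, 4, 4)).astype(np.float32)
        out = HeadOutputs([Tensor(cls)], [Tensor(dist)], [Tensor(ctr)],
                          [grid_points((4, 4), 8)], (8,))
        counts = [len(decode(out, score_thresh=t, nms_iou=0.9, max_dets=1000))
                  for t in (0.0, 0.1, 0.3, 0.5, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_final_score_is_geometric_mean(self):
        out = make_outputs([(1, 1, 1, 0.0, (2, 2, 2, 2))], grid=(2, 2))
        out.ctr_logits[0].data[:] = 0.0
        dets = decode(out, score_thresh=0.05)
        best = max(dets, key=lambda d: d.score)
        np.testing.assert_allclose(best.score, 0.5, atol=1e-6)  # sqrt(.5*.5)


class TestNMS:
    def test_identical_boxes_keep_best(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10]], dtype=float)
        keep = nms(boxes, np.array([0.9, 0.8]), 0.6)
        assert list(keep) == [0]

    def test_matches_brute_force_on_random_boxes(self, rng):
        for _ in range(30):
            n = 5
            xy = rng.uniform(0, 20, size=(n, 2))
            wh = rng.uniform(2, 15, size=(n, 2))
            boxes = np.concatenate([xy, xy + wh], axis=1)
            scores = rng.uniform(0, 1, size=n)
            got = list(nms(boxes, scores, 0.5))
            assert got == brute_force_nms(boxes, scores, 0.5)

    def test_idempotent(self, rng):
        n = 12
        xy = rng.uniform(0, 30, size=(n, 2))
        wh = rng.uniform(2, 10, size=(n, 2))
        boxes = np.concatenate([xy, xy + wh], axis=1)
        scores = rng.uniform(0, 1, size=n)
        keep1 = nms(boxes, scores, 0.5)
        keep2 = keep1[nms(boxes[keep1], scores[keep1], 0.5)]
        assert list(keep1) == list(keep2)


class TestBoxIoU:
    def test_known_values(self):
        assert box_iou_matrix([[0, 0, 2, 2]], [[0, 0, 2, 2]])[0, 0] == 1.0
        assert box_iou_matrix([[0, 0, 1, 1]], [[5, 5, 6, 6]])[0, 0] == 0.0
        np.testing.assert_allclose(
            box_iou_matrix([[0, 0, 2, 2]], [[1, 1, 3, 3]])[0, 0], 1 / 7)

    def test_zero_area_box_gives_zero(self):
        assert box_iou_matrix([[1, 1, 1, 5]], [[0, 0, 4, 4]])[0, 0] == 0.0
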