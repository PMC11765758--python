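"""Coordinate attention: directional pooling, gates, reweighting."""

import numpy as np
import pytest

from capest.autodiff import Tensor
from capest.coordinate_attention import (CABlock, CAGates, ca_apply, ca_block,
                                         ca_gates, pool_directional)
from capest.errors import ConfigurationError, ValidationError

from conftest import numerical_grad, to_float64


def loop_pool(x):
    """Naive per-element oracle for the directional means."""
    c, h, w = x.shape
    zh = np.zeros((c, h))
    zw = np.zeros((c, w))
    for l in range(c):
        for i in range(h):
            zh[l, i] = sum(x[l, i, j] for j in range(w)) / w
        for j in range(w):
            zw[l, j] = sum(x[l, i, j] for i in range(h)) / h
    return zh, zw


def loop_apply(x, gh, gw):
    c, h, w = x.shape
    o = np.zeros_like(x)
    for l in range(c):
        for i in range(h):
            for j in range(w):
                o[l, i, j] = x[l, i, j] * gh[l, i] * gw[l, j]
    return o


class TestPoolDirectional:
    def test_hand_computed_row_and_column_means(self):
        x = np.array([[[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]])
        z = pool_directional(x)
        np.testing.assert_allclose(z.zh.data, [[2.0, 5.0]])
        np.testing.assert_allclose(z.zw.data, [[2.5, 3.5, 4.5]])

    def test_constant_map_pools_to_constant(self):
        x = np.full((2, 3, 4), 7.25)
        z = pool_directional(x)
        np.testing.assert_allclose(z.zh.data, 7.25)
        np.testing.assert_allclose(z.zw.data, 7.25)

    def test_matches_triple_loop_oracle(self, rng):
        x = rng.normal(size=(3, 4, 5))
        z = pool_directional(x)
        zh, zw = loop_pool(x)
        np.testing.assert_allclose(z.zh.data, zh, rtol=1e-6)
        np.testing.assert_allclose(z.zw.data, zw, rtol=1e-6)

    def test_descriptors_bounded_by_channel_range(self, rng):
        x = rng.normal(size=(4, 6, 7))
        z = pool_directional(x)
        for l in range(4):
            lo, hi = x[l].min(), x[l].max()
            assert np.all(z.zh.data[l] >= lo - 1e-9)
            assert np.all(z.zw.data[l] <= hi + 1e-9)

    def test_rejects_non_finite_input(self):
        x = np.ones((1, 2, 2))
        x[0, 0, 0] = np.nan
        with pytest.raises(ValidationError):
            pool_directional(x)


class TestGates:
    def test_zero_restore_weights_give_half_gates(self, rng):
        block = CABlock(4, reduction=2.0, rng=rng)
        for conv in (block.conv_h, block.conv_w):
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        g = ca_gates(pool_directional(rng.normal(size=(4, 3, 5))), block)
        np.testing.assert_allclose(g.gh.data, 0.5)
        np.testing.assert_allclose(g.gw.data, 0.5)
        assert g.gh.shape == (4, 3) and g.gw.shape == (4, 5)

    def test_gates_strictly_inside_unit_interval(self, rng):
        block = CABlock(8, reduction=4.0, rng=rng)
        g = ca_gates(pool_directional(rng.normal(size=(8, 6, 6)) * 3), block)
        for arr in (g.gh.data, g.gw.data):
            assert np.all(arr > 0) and np.all(arr < 1)

    def test_single_channel_scalar_arithmetic(self):
        """Hand-rolled scalar path: one channel, hand-set weights."""
        block = CABlock(1, reduction=1.0, rng=np.random.default_rng(0))
        block.conv_joint.weight.data[:] = 2.0
        block.conv_joint.bias.data[:] = -1.0
        block.conv_h.weight.data[:] = 0.5
        block.conv_h.bias.data[:] = 0.25
        block.conv_w.weight.data[:] = -0.5
        block.conv_w.bias.data[:] = 0.0
        x = np.array([[[1.0, 3.0], [5.0, 7.0]]])   # zh = (2, 6), zw = (3, 5)
        g = ca_gates(pool_directional(x), block)
        sig = lambda v: 1 / (1 + np.exp(-v))
        f = np.maximum(2.0 * np.array([2.0, 6.0, 3.0, 5.0]) - 1.0, 0.0)
        np.testing.assert_allclose(g.gh.data[0], sig(0.5 * f[:2] + 0.25),
                                   rtol=1e-6)
        np.testing.assert_allclose(g.gw.data[0], sig(-0.5 * f[2:]), rtol=1e-6)

    def test_channel_mismatch_raises(self, rng):
        block = CABlock(4, rng=rng)
        z = pool_directional(rng.normal(size=(3, 2, 2)))
        with pytest.raises(ConfigurationError):
            ca_gates(z, block)


class TestApplyAndBlock:
    def test_half_gates_quarter_the_input(self, rng):
        x = rng.normal(size=(2, 3, 4))
        g = CAGates(gh=Tensor(np.full((2, 3), 0.5)),
                    gw=Tensor(np.full((2, 4), 0.5)))
        np.testing.assert_allclose(ca_apply(x, g).data, x / 4.0, rtol=1e-6)

    def test_zero_input_stays_zero(self, rng):
        g = CAGates(gh=Tensor(rng.uniform(0, 1, (2, 3))),
                    gw=Tensor(rng.uniform(0, 1, (2, 4))))
        assert np.all(ca_apply(np.zeros((2, 3, 4)), g).data == 0)

    def test_matches_triple_loop_oracle(self, rng):
        x = rng.normal(size=(2, 3, 4))
        gh = rng.uniform(0, 1, (2, 3))
        gw = rng.uniform(0, 1, (2, 4))
        out = ca_apply(x, CAGates(gh=Tensor(gh), gw=Tensor(gw)))
        np.testing.assert_allclose(out.data, loop_apply(x, gh, gw), rtol=1e-6)

    def test_shape_mismatch_raises(self, rng):
        g = CAGates(gh=Tensor(np.ones((2, 3))), gw=Tensor(np.ones((2, 5))))
        with pytest.raises(ValidationError):
            ca_apply(np.zeros((2, 3, 4)), g)

    def test_block_is_elementwise_contraction(self, rng):
        block = CABlock(4, rng=rng)
        x = rng.normal(size=(4, 5, 6))
        out = ca_block(x, block)
        assert np.all(np.abs(out.data) <= np.abs(x) + 1e-12)

    def test_scalar_closed_form_on_1x1x1_input(self):
        block = CABlock(1, reduction=1.0, rng=np.random.default_rng(3))
        c = 1.7
        wj = block.conv_joint.weight.data.item()
        bj = block.conv_joint.bias.data.item()
        wh = block.conv_h.weight.data.item()
        bh = block.conv_h.bias.data.item()
        ww = block.conv_w.weight.data.item()
        bw = block.conv_w.bias.data.item()
        f = max(wj * c + bj, 0.0)
        sig = lambda v: 1 / (1 + np.exp(-v))
        expected = c * sig(wh * f + bh) * sig(ww * f + bw)
        out = ca_block(np.array([[[c]]]), block)
        np.testing.assert_allclose(out.data.item(), expected, rtol=1e-6)

    def test_gradients_match_central_differences(self, rng):
        block = to_float64(CABlock(2, reduction=2.0, rng=rng))
        x = rng.normal(size=(2, 4, 4))

        def scalar(xv):
            return float((ca_block(Tensor(xv, dtype=np.float64), block) ** 2)
                         .sum().data)

        t = Tensor(x, requires_grad=True, dtype=np.float64)
        (ca_block(t, block) ** 2).sum().backward()
        np.testing.assert_allclose(t.grad, numerical_grad(scalar, x),
                                   rtol=1e-4, atol=1e-8)
        # parameter gradients on the joint transform
        w0 = block.conv_joint.weight.data.copy()

        def scalar_w(wv):
            block.conv_joint.weight.data = wv
            out = scalar(x)
            block.conv_joint.weight.data = w0
            return out

        num = numerical_grad(scalar_w, w0.copy())
        np.testing.assert_allclose(block.conv_joint.weight.grad, num,
                                   rtol=1e-4, atol=1e-8)

    def test_channel_permutation_equivariance(self, rng):
        block = CABlock(3, reduction=1.0, rng=rng)
        x = rng.normal(size=(3, 4, 5)).astype(np.float32)
        perm = np.array([2, 0, 1])
        out = ca_block(x, block).data
        # permute input channels and all channel-indexed parameters
        block.conv_joint.weight.data = block.conv_joint.weight.data[:, perm]
        block.conv_h.weight.data = block.conv_h.weight.data[perm]
        block.conv_h.bias.data = block.conv_h.bias.data[perm]
        block.conv_w.weight.data = block.conv_w.weight.data[perm]
        block.conv_w.bias.data = block.conv_w.bias.data[perm]
        out_p = ca_block(x[perm], block).data
        np.testing.assert_allclose(out_p, out[perm], rtol=1e-5, atol=1e-6)

    def test_parameter_count_formula(self):
        block = CABlock(256, reduction=3.5)
        hidden = block.hidden
        assert hidden == 74
        assert block.num_parameters() == 769 * hidden + 512
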