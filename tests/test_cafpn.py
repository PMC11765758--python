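"""Feature-pyramid construction, fusion, and the plain-FPN ablation."""

import numpy as np
import pytest

from capest.autodiff import Tensor
from capest.backbones import TinyBackbone
from capest.cafpn import CAFPN, FpnConfig, fuse_level, lateral_project, upsample2x
from capest.errors import ConfigurationError
from capest.nn import Conv2d


def plain_fpn_reference(feats, module):
    """Independent re-computation of the plain top-down fusion
    Y_i = C_i(X_i) + Up(Y_{i+1}) with numpy only."""
    lats = []
    for conv, f in zip(module.laterals, feats):
        w = conv.weight.data.reshape(conv.out_channels, -1)
        n, c, h, wd = f.shape
        lat = np.einsum("oc,nchw->nohw", w.reshape(conv.out_channels, c), f)
        lat += conv.bias.data[None, :, None, None]
        lats.append(lat)
    ys = [None, None, lats[2]]
    for i in (1, 0):
        up = np.repeat(np.repeat(ys[i + 1], 2, axis=2), 2, axis=3)
        up = up[:, :, :lats[i].shape[2], :lats[i].shape[3]]
        ys[i] = lats[i] + up
    return ys


class TestPrimitives:
    def test_upsample_doubles_and_replicates(self):
        y = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        out = upsample2x(y).data
        np.testing.assert_array_equal(
            out[0], [[1, 1, 2, 2], [1, 1, 2, 2], [3, 3, 4, 4], [3, 3, 4, 4]])

    def test_upsample_preserves_mean(self, rng):
        y = rng.normal(size=(1, 3, 5, 7))
        assert np.isclose(upsample2x(Tensor(y)).data.mean(), y.mean())

    def test_lateral_identity_initialization(self, rng):
        conv = Conv2d(4, 4, 1, rng=rng)
        conv.weight.data = np.eye(4, dtype=np.float32).reshape(4, 4, 1, 1)
        conv.bias.data[:] = 0
        x = rng.normal(size=(4, 3, 3)).astype(np.float32)
        np.testing.assert_allclose(lateral_project(x, conv).data, x, rtol=1e-6)

    def test_lateral_projects_channels_preserves_space(self, rng):
        conv = Conv2d(512, 256, 1, rng=rng)
        x = rng.normal(size=(1, 512, 7, 5)).astype(np.float32)
        assert lateral_project(x, conv).shape == (1, 256, 7, 5)

    def test_lateral_hand_mix(self):
        conv = Conv2d(2, 1, 1)
        conv.weight.data = np.array([[[[2.0]], [[-1.0]]]], dtype=np.float32)
        conv.bias.data[:] = 0.5
        x = np.array([[[1.0, 2.0], [3.0, 4.0]],
                      [[5.0, 6.0], [7.0, 8.0]]])
        out = lateral_project(x, conv).data[0]
        np.testing.assert_allclose(out, 2 * x[0] - x[1] + 0.5)


class TestFusion:
    def test_zero_lateral_passes_upsampled_upper(self, rng):
        cfg = FpnConfig(width=8, use_ca=False)
        upper = Tensor(rng.normal(size=(1, 8, 3, 3)).astype(np.float32))
        lateral = Tensor(np.zeros((1, 8, 6, 6), dtype=np.float32))
        out = fuse_level(lateral, upper, cfg)
        np.testing.assert_allclose(out.data, upsample2x(upper).data)

    def test_forced_half_gates_quarter_the_upsampled_map(self, rng):
        from capest.coordinate_attention import CABlock
        cfg = FpnConfig(width=4, use_ca=True)
        ca = CABlock(4, rng=rng)
        for conv in (ca.conv_h, ca.conv_w):
            conv.weight.data[:] = 0
            conv.bias.data[:] = 0
        lateral = Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32))
        upper = Tensor(rng.normal(size=(1, 4, 2, 2)).astype(np.float32))
        out = fuse_level(lateral, upper, cfg, ca)
        np.testing.assert_allclose(
            out.data, lateral.data + upsample2x(upper).data / 4.0, rtol=1e-5)

    def test_ca_on_requires_block(self, rng):
        cfg = FpnConfig(width=4, use_ca=True)
        with pytest.raises(ConfigurationError):
            fuse_level(Tensor(np.zeros((1, 4, 4, 4))),
                       Tensor(np.zeros((1, 4, 2, 2))), cfg, None)


class TestBuildPyramid:
    def test_level_shapes_for_800x608_input(self, rng):
        """Strides 8/16/32/64/128 with ceil-division spatial sizes."""
        cfg = FpnConfig(width=16, use_ca=False)
        fpn = CAFPN((32, 48, 64), cfg, rng=rng)
        shapes = [(100, 76), (50, 38), (25, 19)]
        feats = [Tensor(rng.normal(size=(1, c, h, w)).astype(np.float32))
                 for c, (h, w) in zip((32, 48, 64), shapes)]
        pyr = fpn(feats)
        got = [tuple(p.shape[2:]) for p in pyr]
        assert got == [(100, 76), (50, 38), (25, 19), (13, 10), (7, 5)]
        assert all(p.shape[1] == 16 for p in pyr)

    def test_channel_uniformity_default_width(self, rng):
        fpn = CAFPN((8, 8, 8), FpnConfig(width=256, use_ca=False), rng=rng)
        feats = [Tensor(rng.normal(size=(1, 8, s, s)).astype(np.float32))
                 for s in (16, 8, 4)]
        assert all(p.shape[1] == 256 for p in fpn(feats))

    def test_ca_off_reproduces_plain_fpn_reference(self, rng):
        cfg = FpnConfig(width=8, use_ca=False)
        fpn = CAFPN((4, 6, 8), cfg, rng=rng)
        fpn.set_identity_smoothing()
        feats_np = [rng.normal(size=(2, c, s, s)).astype(np.float32)
                    for c, s in ((4, 9), (6, 5), (8, 3))]  # odd sizes too
        pyr = fpn([Tensor(f) for f in feats_np])
        ref = plain_fpn_reference(feats_np, fpn)
        for level in range(3):
            np.testing.assert_allclose(pyr[level].data, ref[level],
                                       rtol=1e-5, atol=1e-5)

    def test_ca_toggle_shares_weights_and_matches_when_gates_forced_to_one(self, rng):
        """With CA blocks bypassed (gates == 1 is impossible; instead the
        use_ca flag off) the same lateral/smoothing weights give identical
        pyramids — the ablation contract."""
        fpn_ca = CAFPN((4, 6, 8), FpnConfig(width=8, use_ca=True), rng=rng)
        fpn_off = CAFPN((4, 6, 8), FpnConfig(width=8, use_ca=False),
                        rng=np.random.default_rng(7))
        # share the non-CA weights
        for a, b in zip(fpn_off.laterals + fpn_off.smooth + fpn_off.extras,
                        fpn_ca.laterals + fpn_ca.smooth + fpn_ca.extras):
            a.weight.data = b.weight.data.copy()
            a.bias.data = b.bias.data.copy()
        fpn_ca.cfg = FpnConfig(width=8, use_ca=False)  # disable at run time
        feats = [Tensor(rng.normal(size=(1, c, s, s)).astype(np.float32))
                 for c, s in ((4, 8), (6, 4), (8, 2))]
        pyr_a = fpn_ca(feats)
        pyr_b = fpn_off(feats)
        for a, b in zip(pyr_a, pyr_b):
            np.testing.assert_array_equal(a.data, b.data)

    def test_zero_features_zero_pyramid_with_zero_bias(self, rng):
        fpn = CAFPN((4, 6, 8), FpnConfig(width=8, use_ca=False), rng=rng)
        for conv in fpn.laterals + fpn.smooth + fpn.extras:
            conv.bias.data[:] = 0
        feats = [Tensor(np.zeros((1, c, s, s), dtype=np.float32))
                 for c, s in ((4, 8), (6, 4), (8, 2))]
        for p in fpn(feats):
            np.testing.assert_array_equal(p.data, 0)

    def test_requires_three_levels(self, rng):
        with pytest.raises(ConfigurationError):
            CAFPN((4, 8), FpnConfig(width=8), rng=rng)

    def test_parameter_delta_is_three_ca_blocks(self, rng):
        from capest.coordinate_attention import CABlock
        cfg_on = FpnConfig(width=64, use_ca=True, ca_reduction=4.0)
        cfg_off = FpnConfig(width=64, use_ca=False)
        on = CAFPN((16, 32, 64), cfg_on, rng=rng)
        off = CAFPN((16, 32, 64), cfg_off, rng=rng)
        one_block = CABlock(64, reduction=4.0).num_parameters()
        assert on.num_parameters() - off.num_parameters() == 3 * one_block

    def test_backbone_to_pyramid_integration(self, rng):
        bb = TinyBackbone(rng=rng)
        fpn = CAFPN(bb.out_channels, FpnConfig(width=32, extra_levels=0),
                    rng=rng)
        x = Tensor(rng.normal(size=(1, 3, 128, 128)).astype(np.float32))
        pyr = fpn(bb(x))
        assert [tuple(p.shape[2:]) for p in pyr] == [(16, 16), (8, 8), (4, 4)]
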