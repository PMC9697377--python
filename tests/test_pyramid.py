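"""Attention pyramid: primitives, fusion, and equivalence to a plain FPN."""

import numpy as np
import pytest

from maizedet.autodiff import Tensor, upsample2x_nearest
from maizedet.backbone import BackboneConfig, Backbone, FeatureMap
from maizedet.nn import Conv2d
from maizedet.pyramid import (AMFFP, PyramidConfig, WeightGenerator,
                              attention_weights, build_pyramid, fuse_level,
                              lateral_project)


def _feats(rng, channels=(4, 6, 8, 8), size=16):
    """Backbone-like stage features C2..C5 at strides 4,8,16,32."""
    out = {}
    s = size
    for i, (name, c) in enumerate(zip(("C2", "C3", "C4", "C5"), channels)):
        out[name] = FeatureMap(rng.normal(size=(1, c, s, s)), stride=4 * 2 ** i)
        s //= 2
    return out


def conv_ref(x, w, b, pad):
    """Nested-loop cross-correlation reference (scipy-based)."""
    from scipy.signal import correlate

    N, C, H, W = x.shape
    F = w.shape[0]
    out = np.zeros((N, F, H + 2 * pad - w.shape[2] + 1,
                    W + 2 * pad - w.shape[3] + 1))
    for f in range(F):
        for c in range(C):
            out[0, f] += correlate(np.pad(x[0, c], pad), w[f, c], mode="valid")
        out[0, f] += b[f]
    return out


def plain_fpn_reference(feats, neck):
    """Independent plain-FPN (alpha = 1) built from neck's own weights."""
    lat = {}
    for s, conv in zip(neck.lateral_stages, neck.laterals):
        lat[s] = conv_ref(feats[s].values.data, conv.w.data, conv.b.data, 0)
    names = list(neck.lateral_stages)
    fused = {names[-1]: lat[names[-1]]}
    for i in range(len(names) - 2, -1, -1):
        upper = fused[names[i + 1]]
        up = upper.repeat(2, axis=2).repeat(2, axis=3)
        fused[names[i]] = lat[names[i]] + up
    out = {}
    for i, s in enumerate(names):
        sm = neck.smooth[i]
        out[f"P{i + 2}"] = conv_ref(fused[s], sm.w.data, sm.b.data, 1)
    return out


class TestPrimitives:
    def test_identity_lateral_projection(self, rng):
        conv = Conv2d(rng, 3, 3, 1)
        conv.w.data[...] = np.eye(3).reshape(3, 3, 1, 1)
        conv.b.data[...] = 0.0
        x = FeatureMap(rng.normal(size=(1, 3, 5, 5)), stride=4)
        out = lateral_project(x, conv)
        np.testing.assert_allclose(out.data, x.values.data)

    def test_lateral_preserves_spatial_dims(self, rng):
        conv = Conv2d(rng, 5, 8, 1)
        out = lateral_project(Tensor(rng.normal(size=(1, 5, 7, 9))), conv)
        assert out.shape == (1, 8, 7, 9)

    def test_lateral_rejects_non_1x1(self, rng):
        with pytest.raises(ValueError, match="1x1"):
            lateral_project(Tensor(np.zeros((1, 3, 4, 4))), Conv2d(rng, 3, 8, 3))

    def test_lateral_matches_per_pixel_matmul(self, rng):
        conv = Conv2d(rng, 4, 6, 1)
        x = rng.normal(size=(1, 4, 3, 3))
        out = lateral_project(Tensor(x), conv).data
        W = conv.w.data[:, :, 0, 0]
        for i in range(3):
            for j in range(3):
                np.testing.assert_allclose(out[0, :, i, j],
                                           W @ x[0, :, i, j] + conv.b.data,
                                           atol=1e-12)

    def test_upsample_replicates_blocks(self):
        up = upsample2x_nearest(Tensor(np.array([[[[7.0]]]])))
        np.testing.assert_allclose(up.data, np.full((1, 1, 2, 2), 7.0))

    def test_upsample_sum_quadruples(self, rng):
        x = Tensor(rng.normal(size=(1, 2, 3, 5)))
        assert upsample2x_nearest(x).data.sum() == pytest.approx(4 * x.data.sum())

    def test_upsample_downsample_roundtrip(self, rng):
        x = rng.normal(size=(1, 2, 4, 4))
        up = upsample2x_nearest(Tensor(x)).data
        np.testing.assert_array_equal(up[..., ::2, ::2], x)


class TestAttentionWeights:
    def test_zero_generator_gives_half_everywhere(self, rng):
        gen = WeightGenerator(rng, 6, 2, 1)
        for conv in (gen.conv1, gen.conv3):
            conv.w.data[...] = 0.0
            conv.b.data[...] = 0.0
        a = attention_weights(Tensor(rng.normal(size=(1, 6, 4, 4))), gen)
        np.testing.assert_allclose(a.data, 0.5)

    def test_output_strictly_inside_unit_interval(self, rng):
        gen = WeightGenerator(rng, 4, 2, 1)
        a = attention_weights(Tensor(5 * rng.normal(size=(1, 4, 6, 6))), gen).data
        assert a.min() > 0.0 and a.max() < 1.0

    def test_composition_equals_sequential_primitives(self, rng):
        gen = WeightGenerator(rng, 4, 3, 1)
        x = rng.normal(size=(1, 4, 5, 5))
        got = attention_weights(Tensor(x), gen).data
        h = conv_ref(x, gen.conv1.w.data, gen.conv1.b.data, 0)
        h = np.maximum(h, 0.0)
        h = conv_ref(h, gen.conv3.w.data, gen.conv3.b.data, 1)
        np.testing.assert_allclose(got, 1 / (1 + np.exp(-h)), atol=1e-12)


class TestFuseLevel:
    def test_alpha_one_is_plain_addition(self, rng):
        lat = rng.normal(size=(1, 3, 4, 4))
        up = rng.normal(size=(1, 3, 4, 4))
        out = fuse_level(Tensor(lat), Tensor(up), np.ones((1, 1, 1, 1)))
        np.testing.assert_allclose(out.data, lat + up)

    def test_alpha_zero_returns_lateral(self, rng):
        lat = rng.normal(size=(1, 3, 4, 4))
        out = fuse_level(Tensor(lat), Tensor(rng.normal(size=(1, 3, 4, 4))),
                         np.zeros((1, 1, 1, 1)))
        np.testing.assert_allclose(out.data, lat)

    def test_elementwise_against_loop(self, rng):
        lat = rng.normal(size=(1, 2, 3, 3))
        up = rng.normal(size=(1, 2, 3, 3))
        alpha = rng.random((1, 1, 3, 3))
        out = fuse_level(Tensor(lat), Tensor(up), alpha).data
        for c in range(2):
            for i in range(3):
                for j in range(3):
                    assert out[0, c, i, j] == pytest.approx(
                        lat[0, c, i, j] + alpha[0, 0, i, j] * up[0, c, i, j])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="fuse"):
            fuse_level(Tensor(np.zeros((1, 2, 4, 4))),
                       Tensor(np.zeros((1, 2, 8, 8))), 1.0)


class TestBuildPyramid:
    def test_level_sizes_from_64px_input(self, rng):
        feats = _feats(rng)
        neck = AMFFP(PyramidConfig(channels=8, hidden_channels=2, seed=0),
                     {k: v.shape[1] for k, v in feats.items()})
        pyr = build_pyramid(feats, neck)
        assert [pyr[f"P{i}"].shape[2] for i in range(2, 7)] == [16, 8, 4, 2, 1]
        assert [pyr[f"P{i}"].stride for i in range(2, 7)] == [4, 8, 16, 32, 64]
        assert all(pyr[k].shape[1] == 8 for k in pyr.keys())

    def test_alpha_maps_strictly_in_unit_interval(self, rng):
        feats = _feats(rng)
        neck = AMFFP(PyramidConfig(channels=8, hidden_channels=2, seed=0),
                     {k: v.shape[1] for k, v in feats.items()})
        pyr = build_pyramid(feats, neck)
        assert set(pyr.alpha_maps) == {"P2", "P3", "P4"}
        for a in pyr.alpha_maps.values():
            assert a.min() > 0.0 and a.max() < 1.0

    def test_alpha_maps_deterministic(self, rng):
        feats = _feats(rng)
        neck = AMFFP(PyramidConfig(channels=8, hidden_channels=2, seed=0),
                     {k: v.shape[1] for k, v in feats.items()})
        a1 = build_pyramid(feats, neck).alpha_maps
        a2 = build_pyramid(feats, neck).alpha_maps
        for k in a1:
            np.testing.assert_array_equal(a1[k], a2[k])

    def test_missing_stage_rejected(self, rng):
        feats = _feats(rng)
        del feats["C4"]
        neck = AMFFP(PyramidConfig(channels=8, seed=0),
                     {"C2": 4, "C3": 6, "C4": 8, "C5": 8})
        with pytest.raises(ValueError, match="C4"):
            build_pyramid(feats, neck)

    def test_bypass_reduces_to_plain_fpn(self, rng):
        """alpha forced to 1 reproduces an independent FPN to <1e-5."""
        for trial in range(10):
            feats = _feats(rng)
            neck = AMFFP(PyramidConfig(channels=8, hidden_channels=2,
                                       alpha_bypass=True, seed=trial),
                         {k: v.shape[1] for k, v in feats.items()})
            pyr = build_pyramid(feats, neck)
            ref = plain_fpn_reference(feats, neck)
            for lvl, expect in ref.items():
                got = pyr[lvl].values.data
                assert np.abs(got - expect).max() < 1e-5

    def test_literal_subsample_variant_layout(self, rng):
        feats = _feats(rng)
        neck = AMFFP(PyramidConfig(channels=8, hidden_channels=2,
                                   literal_subsample_variant=True, seed=0),
                     {k: v.shape[1] for k, v in feats.items()})
        pyr = neck(feats)
        # laterals C2..C4; P5 and P6 both obtained by subsampling
        assert [pyr[f"P{i}"].shape[2] for i in range(2, 7)] == [16, 8, 4, 2, 1]
        assert pyr["P5"].stride == 32 and pyr["P6"].stride == 64

    def test_per_channel_attention_variant(self, rng):
        feats = _feats(rng)
        neck = AMFFP(PyramidConfig(channels=8, hidden_channels=2,
                                   attention_channels=8, seed=0),
                     {k: v.shape[1] for k, v in feats.items()})
        pyr = neck(feats)
        assert all(a.shape[1] == 8 for a in pyr.alpha_maps.values())


class TestWithRealBackbone:
    def test_end_to_end_shapes(self, rng):
        bb = Backbone(BackboneConfig(depth="tiny", seed=0))
        neck = AMFFP(PyramidConfig(channels=16, hidden_channels=4, seed=1),
                     bb.out_channels)
        pyr = neck(bb(Tensor(rng.normal(size=(1, 3, 64, 64)))))
        assert [pyr[f"P{i}"].shape[2:] for i in range(2, 7)] == \
            [(16, 16), (8, 8), (4, 4), (2, 2), (1, 1)]
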