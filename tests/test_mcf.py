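"""Multi-scale Cavity Fusion block: branches, projection, calibration, fusion."""

import numpy as np
import pytest

from hhbsnet.mcf import DILATION_RATES, MCF
from hhbsnet.autodiff import Tensor

from _oracles import naive_conv2d


def identity_pointwise(conv):
    """Set a 1x1 CxC conv to the identity map."""
    conv.weight.data[...] = 0.0
    for c in range(conv.weight.data.shape[0]):
        conv.weight.data[c, c, 0, 0] = 1.0
    if conv.bias is not None:
        conv.bias.data[...] = 0.0


def identity_bn(bn):
    bn.gamma.data[...] = 1.0
    bn.beta.data[...] = 0.0
    bn.running_mean[...] = 0.0
    bn.running_var[...] = 1.0 - bn.eps  # so gamma/sqrt(var+eps) == 1 exactly


class TestBranches:
    def test_constant_input_through_identity_pooling_branch(self, seeded_init):
        """Global mean of a constant plane is the constant itself."""
        block = MCF(4).eval()
        identity_pointwise(block.branch5_conv)
        x = np.full((4, 8, 8), 2.5)
        b5 = block.branches(x)[4]
        np.testing.assert_allclose(b5.data, 2.5, atol=1e-12)

    def test_pooling_branch_is_spatially_constant(self, seeded_init, rng):
        block = MCF(4).eval()
        b5 = block.branches(rng.normal(size=(4, 8, 8)))[4].data
        for c in range(4):
            assert np.ptp(b5[c]) == 0.0

    @pytest.mark.parametrize("rate", DILATION_RATES)
    def test_impulse_response_taps_at_dilation_offsets(self, seeded_init, rate):
        """A ones depthwise 3x3 kernel at rate r fires only at offsets {-r,0,r}."""
        branch = {6: "branch2", 12: "branch3", 18: "branch4"}[rate]
        block = MCF(4).eval()
        sub = getattr(block, branch)
        sub.depthwise.weight.data[...] = 1.0
        identity_pointwise(sub.pointwise)
        identity_bn(sub.bn)
        size = 2 * rate + 9
        x = np.zeros((4, size, size))
        center = size // 2
        x[:, center, center] = 1.0
        out = sub(Tensor(x).reshape(1, 4, size, size)).data[0, 0]
        nonzero = np.argwhere(out != 0.0) - center
        expected = {(dy, dx) for dy in (-rate, 0, rate) for dx in (-rate, 0, rate)}
        assert set(map(tuple, nonzero)) == expected

    @pytest.mark.parametrize("rate", DILATION_RATES)
    def test_effective_receptive_extent(self, rate):
        assert (3 - 1) * rate + 1 == {6: 13, 12: 25, 18: 37}[rate]

    def test_dilated_branches_match_naive_convolution(self, seeded_init, rng):
        """Depthwise dilated stage equals the nested-loop oracle, C=4, 16x16."""
        block = MCF(4).eval()
        x = rng.normal(size=(4, 16, 16))
        for branch, rate in [(block.branch2, 6), (block.branch3, 12),
                             (block.branch4, 18)]:
            expected = naive_conv2d(x, branch.depthwise.weight.data,
                                    branch.depthwise.bias.data,
                                    padding=rate, dilation=rate, groups=4)
            from hhbsnet.autodiff import conv2d
            got = branch.depthwise(Tensor(x).reshape(1, 4, 16, 16)).data[0]
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_branch_shapes(self, seeded_init, rng):
        block = MCF(4).eval()
        outs = block.branches(rng.normal(size=(4, 16, 16)))
        assert all(o.shape == (4, 16, 16) for o in outs)


class TestConcatProject:
    def test_shape_contract(self, seeded_init, rng):
        block = MCF(4).eval()
        maps = [rng.normal(size=(4, 8, 8)) for _ in range(5)]
        assert block.concat_project(maps).shape == (4, 8, 8)

    def test_block_averaging_projection_returns_input(self, seeded_init, rng):
        """Averaging weights over 5 identical branch copies reproduce x."""
        block = MCF(4).eval()
        block.proj_in.weight.data[...] = 0.0
        block.proj_in.bias.data[...] = 0.0
        for c in range(4):
            for b in range(5):
                block.proj_in.weight.data[c, b * 4 + c, 0, 0] = 0.2
        x = rng.normal(size=(4, 8, 8))
        out = block.concat_project([x] * 5)
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_matches_per_pixel_linear_map_oracle(self, seeded_init, rng):
        block = MCF(4).eval()
        maps = [rng.normal(size=(4, 6, 6)) for _ in range(5)]
        stacked = np.concatenate(maps, axis=0)        # [20, 6, 6]
        w = block.proj_in.weight.data[:, :, 0, 0]     # [4, 20]
        b = block.proj_in.bias.data
        expected = np.einsum("ok,khw->ohw", w, stacked) + b[:, None, None]
        np.testing.assert_allclose(block.concat_project(maps).data,
                                   expected, atol=1e-10)

    def test_mismatched_shapes_raise(self, seeded_init, rng):
        block = MCF(4).eval()
        maps = [rng.normal(size=(4, 8, 8))] * 4 + [rng.normal(size=(4, 4, 4))]
        with pytest.raises(ValueError, match="equally shaped"):
            block.concat_project(maps)


class TestCalibration:
    def test_zero_weights_halve_channel_calibration(self, seeded_init, rng):
        block = MCF(4).eval()
        for layer in (block.ca_fc1, block.ca_fc2):
            layer.weight.data[...] = 0.0
            layer.bias.data[...] = 0.0
        f = rng.normal(size=(4, 5, 5))
        np.testing.assert_allclose(block.channel_calibration(f).data,
                                   0.5 * f, atol=1e-12)

    def test_pooled_vector_of_constant_planes(self, seeded_init):
        """Channel planes at 1, 2, 3, 4 pool to exactly (1, 2, 3, 4)."""
        f = np.stack([np.full((6, 6), v) for v in (1.0, 2.0, 3.0, 4.0)])
        np.testing.assert_array_equal(f.mean(axis=(1, 2)), [1, 2, 3, 4])

    def test_channel_calibration_matches_direct_formula(self, seeded_init, rng):
        block = MCF(4).eval()
        f = rng.normal(size=(4, 5, 5))
        pooled = f.mean(axis=(1, 2))
        h = np.maximum(pooled @ block.ca_fc1.weight.data + block.ca_fc1.bias.data, 0)
        gate = 1 / (1 + np.exp(-(h @ block.ca_fc2.weight.data
                                 + block.ca_fc2.bias.data)))
        np.testing.assert_allclose(block.channel_calibration(f).data,
                                   gate[:, None, None] * f, atol=1e-10)

    def test_zero_conv_halves_spatial_calibration(self, seeded_init, rng):
        block = MCF(4).eval()
        block.sa_conv.weight.data[...] = 0.0
        block.sa_conv.bias.data[...] = 0.0
        f = rng.normal(size=(4, 4, 4))
        np.testing.assert_allclose(block.spatial_calibration(f).data,
                                   0.5 * f, atol=1e-12)

    def test_spatial_calibration_matches_direct_formula(self, seeded_init, rng):
        block = MCF(4).eval()
        f = rng.normal(size=(4, 4, 4))
        mean_map = f.mean(axis=0)
        max_map = f.max(axis=0)
        w = block.sa_conv.weight.data[0, :, 0, 0]
        gate = 1 / (1 + np.exp(-(w[0] * mean_map + w[1] * max_map
                                 + block.sa_conv.bias.data[0])))
        np.testing.assert_allclose(block.spatial_calibration(f).data,
                                   gate[None] * f, atol=1e-10)

    def test_constant_input_mean_and_max_maps(self):
        f = np.full((3, 4, 4), 1.75)
        np.testing.assert_array_equal(f.mean(axis=0), np.full((4, 4), 1.75))
        np.testing.assert_array_equal(f.max(axis=0), np.full((4, 4), 1.75))

    def test_both_gates_bounded_in_unit_interval(self, seeded_init, rng):
        block = MCF(4).eval()
        f = rng.normal(size=(4, 6, 6)) * 10
        cal = block.channel_calibration(f).data
        nonzero = np.abs(f) > 1e-12
        ratio = cal[nonzero] / f[nonzero]
        assert np.all(ratio > 0) and np.all(ratio < 1)


class TestFuse:
    def test_all_zero_inputs_give_bias_map(self, seeded_init):
        block = MCF(4).eval()
        block.proj_out.bias.data[...] = 0.0
        z = np.zeros((4, 4, 4))
        np.testing.assert_allclose(block.fuse(z, z, z).data, 0.0)

    def test_identity_projection_pure_residual(self, seeded_init, rng):
        block = MCF(4).eval()
        identity_pointwise(block.proj_out)
        z = np.zeros((4, 4, 4))
        orig = rng.normal(size=(4, 4, 4))
        np.testing.assert_allclose(block.fuse(z, z, orig).data, orig, atol=1e-12)

    def test_matches_addition_plus_linear_map_oracle(self, seeded_init, rng):
        block = MCF(4).eval()
        fc, fs, orig = (rng.normal(size=(4, 3, 3)) for _ in range(3))
        summed = fc + fs + orig
        w = block.proj_out.weight.data[:, :, 0, 0]
        b = block.proj_out.bias.data
        expected = np.einsum("ok,khw->ohw", w, summed) + b[:, None, None]
        np.testing.assert_allclose(block.fuse(fc, fs, orig).data,
                                   expected, atol=1e-10)

    def test_residual_toggle(self, seeded_init, rng):
        z = np.zeros((4, 4, 4))
        orig = rng.normal(size=(4, 4, 4))
        block = MCF(4, residual=False).eval()
        identity_pointwise(block.proj_out)
        np.testing.assert_allclose(block.fuse(z, z, orig).data, 0.0, atol=1e-12)

    def test_shape_mismatch_raises(self, seeded_init, rng):
        block = MCF(4).eval()
        with pytest.raises(ValueError, match="equal shapes"):
            block.fuse(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)),
                       np.zeros((4, 2, 2)))


class TestForward:
    @pytest.mark.parametrize("c", [4, 8, 16])
    @pytest.mark.parametrize("hw", [8, 16, 32])
    def test_shape_preserved(self, seeded_init, rng, c, hw):
        block = MCF(c).eval()
        assert block(rng.normal(size=(c, hw, hw))).shape == (c, hw, hw)

    def test_output_finite_for_bounded_input(self, seeded_init, rng):
        block = MCF(8).eval()
        out = block(rng.uniform(-3, 3, size=(8, 32, 32))).data
        assert np.all(np.isfinite(out))

    def test_composition_equals_chained_stages(self, seeded_init, rng):
        block = MCF(8).eval()
        x = rng.normal(size=(8, 16, 16))
        merged = block.concat_project(block.branches(x))
        expected = block.fuse(block.channel_calibration(merged),
                              block.spatial_calibration(merged), merged)
        np.testing.assert_allclose(block(x).data, expected.data, atol=1e-12)

    def test_translation_equivariance_with_wrap_padding(self, seeded_init, rng):
        """Circularly shifting a periodic input shifts the output identically."""
        block = MCF(4, padding_mode="wrap").eval()
        x = rng.normal(size=(4, 24, 24))
        shift = (5, 9)
        shifted = np.roll(x, shift, axis=(1, 2))
        out = block(x).data
        out_shifted = block(shifted).data
        np.testing.assert_allclose(out_shifted, np.roll(out, shift, axis=(1, 2)),
                                   atol=1e-9)
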