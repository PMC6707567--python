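import numpy as np
import pytest

from busseg.blocks import (
    BRIDGE_DILATIONS,
    AttentionGateSpec,
    DilatedConvSpec,
    ResidualUnitSpec,
    attention_gate,
    dilated_bridge,
    dilated_conv,
    init_attention_gate_weights,
    init_dilated_conv_weights,
    init_residual_unit_weights,
    receptive_field_side,
    residual_unit,
)

import oracles


class TestReceptiveField:
    @pytest.mark.parametrize("r,expected", [
        (1, 3), (2, 7), (4, 15), (8, 31), (16, 63), (32, 127),
    ])
    def test_printed_sequence_k3(self, r, expected):
        assert receptive_field_side(3, r) == expected

    def test_strictly_increasing_odd(self):
        sides = [receptive_field_side(3, r) for r in BRIDGE_DILATIONS]
        assert all(b > a for a, b in zip(sides, sides[1:]))
        assert all(s % 2 == 1 for s in sides)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            receptive_field_side(3, 0)
        with pytest.raises(ValueError):
            receptive_field_side(0, 1)


class TestDilatedConv:
    def test_r1_equals_standard_convolution(self, rng):
        x = rng.normal(size=(6, 6, 2)).astype(np.float32)
        spec = DilatedConvSpec(kernel_size_K=3, dilation_r=1, filters=3)
        w = init_dilated_conv_weights(rng, 2, spec)
        out = dilated_conv(x, spec, w)
        ref = oracles.dilated_conv_loop(x, w["kernel"], w["bias"], dilation=1)
        assert np.abs(out - ref).max() <= 1e-6

    def test_size_preserved_4x4_k3_r2(self, rng):
        x = rng.normal(size=(4, 4, 1)).astype(np.float32)
        spec = DilatedConvSpec(kernel_size_K=3, dilation_r=2, filters=1)
        out = dilated_conv(x, spec, init_dilated_conv_weights(rng, 1, spec))
        assert out.shape == (4, 4, 1)

    def test_matches_loop_oracle_5x5_r2(self, rng):
        x = rng.normal(size=(5, 5, 1))
        spec = DilatedConvSpec(kernel_size_K=3, dilation_r=2, filters=1)
        w = init_dilated_conv_weights(rng, 1, spec)
        w["bias"] = rng.normal(size=1).astype(np.float32)
        out = dilated_conv(x, spec, w)
        ref = oracles.dilated_conv_loop(x, w["kernel"], w["bias"], dilation=2)
        assert np.abs(out - ref).max() <= 1e-5

    def test_invalid_dilation_rejected(self):
        with pytest.raises(ValueError):
            DilatedConvSpec(kernel_size_K=3, dilation_r=0, filters=1)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            DilatedConvSpec(kernel_size_K=4, dilation_r=1, filters=1)


class TestResidualUnit:
    def test_zero_main_branch_identity(self, rng):
        # F = 0 with an identity shortcut leaves non-negative inputs intact
        x = rng.random((5, 5, 3)).astype(np.float32)
        spec = ResidualUnitSpec(filters_n=3, stride_S=1)
        w = {
            "conv1": np.zeros((3, 3, 3, 3), dtype=np.float32),
            "conv2": np.zeros((3, 3, 3, 3), dtype=np.float32),
        }
        out = residual_unit(x, spec, w)
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_downsampling_shape_64_to_32(self, rng):
        x = rng.random((64, 64, 64)).astype(np.float32)
        spec = ResidualUnitSpec(filters_n=128, stride_S=2)
        w = init_residual_unit_weights(rng, 64, spec)
        assert residual_unit(x, spec, w).shape == (32, 32, 128)

    def test_single_pixel_matches_straight_line(self, rng):
        x = rng.normal(size=(1, 1, 1)) * 0.1
        spec = ResidualUnitSpec(filters_n=1, stride_S=1)
        w = init_residual_unit_weights(rng, 1, spec)
        w["bn1"] = {"gamma": rng.random(1) + 0.5, "beta": rng.normal(size=1),
                    "mean": rng.normal(size=1) * 0.1, "var": rng.random(1) + 0.5}
        out = residual_unit(x, spec, w)
        ref = oracles.residual_unit_loop(x, w, stride=1)
        assert np.abs(out - ref).max() <= 1e-5

    def test_missing_projection_raises(self, rng):
        x = rng.random((4, 4, 2)).astype(np.float32)
        spec = ResidualUnitSpec(filters_n=5, stride_S=1)
        w = init_residual_unit_weights(rng, 2, spec)
        del w["shortcut"]
        with pytest.raises(ValueError, match="channels"):
            residual_unit(x, spec, w)

    def test_decoder_spec_requires_stride_1(self):
        with pytest.raises(ValueError):
            ResidualUnitSpec(filters_n=8, stride_S=2, role="decoder")

    def test_jacobian_is_one_plus_main_branch(self, rng):
        # d(out)/d(in) == 1 + d(F)/d(in) at a point where the post-add
        # ReLU is in its linear region
        spec = ResidualUnitSpec(filters_n=1, stride_S=1)
        w = init_residual_unit_weights(rng, 1, spec)
        w["bn2"] = {"beta": np.array([1.0])}  # push the output positive

        def unit(v):
            return residual_unit(np.array([[[v]]], dtype=np.float64),
                                 spec, w)[0, 0, 0]

        def main_branch(v):
            wo = dict(w)
            return oracles.residual_unit_loop(
                np.array([[[v]]]), wo, stride=1,
                activation_after_add=False)[0, 0, 0] - v

        x0, eps = 0.3, 1e-3
        assert unit(x0) > 0.1
        j_unit = (unit(x0 + eps) - unit(x0 - eps)) / (2 * eps)
        j_main = (main_branch(x0 + eps) - main_branch(x0 - eps)) / (2 * eps)
        assert j_unit == pytest.approx(1.0 + j_main, abs=1e-4)


class TestDilatedBridge:
    def _specs(self, filters=2):
        return [DilatedConvSpec(3, r, filters) for r in BRIDGE_DILATIONS]

    def test_output_doubles_spatial_size(self, rng):
        x = rng.random((4, 4, 2)).astype(np.float32)
        specs = self._specs()
        ws = [init_dilated_conv_weights(rng, 2, s) for s in specs]
        assert dilated_bridge(x, specs, ws).shape == (8, 8, 2)

    def test_zero_weights_zero_output(self):
        x = np.ones((4, 4, 2), dtype=np.float32)
        specs = self._specs()
        ws = [{"kernel": np.zeros((3, 3, 2, 2), dtype=np.float32)}
              for _ in specs]
        assert np.all(dilated_bridge(x, specs, ws) == 0)

    def test_equals_sum_of_branches_upsampled(self, rng):
        x = np.zeros((5, 5, 1), dtype=np.float32)
        x[2, 2, 0] = 1.0  # impulse
        specs = self._specs(filters=1)
        ws = [init_dilated_conv_weights(rng, 1, s) for s in specs]
        out = dilated_bridge(x, specs, ws)
        branch_sum = sum(dilated_conv(x, s, w) for s, w in zip(specs, ws))
        expected = branch_sum.repeat(2, axis=0).repeat(2, axis=1)
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_wrong_dilations_rejected(self, rng):
        specs = [DilatedConvSpec(3, r, 1) for r in (1, 2, 3, 8, 16, 32)]
        with pytest.raises(ValueError, match="dilations"):
            dilated_bridge(np.zeros((4, 4, 1)), specs,
                           [init_dilated_conv_weights(rng, 1, s) for s in specs])


class TestAttentionGate:
    def test_alpha_in_unit_interval(self, rng):
        h = rng.normal(size=(4, 4, 3)) * 10
        g = rng.normal(size=(4, 4, 2)) * 10
        spec = AttentionGateSpec(intermediate_channels=2)
        w = init_attention_gate_weights(rng, 3, 2, spec)
        _, alpha = attention_gate(h, g, spec, w, return_alpha=True)
        assert alpha.shape == (4, 4, 1)
        # closed interval: float32 saturates the sigmoid at extreme logits
        assert np.all(alpha >= 0) and np.all(alpha <= 1)

    def test_zero_final_kernel_halves_h(self, rng):
        h = rng.normal(size=(3, 3, 2))
        g = rng.normal(size=(3, 3, 2))
        spec = AttentionGateSpec(intermediate_channels=2)
        w = init_attention_gate_weights(rng, 2, 2, spec)
        w["Wk"] = np.zeros_like(w["Wk"])
        out, alpha = attention_gate(h, g, spec, w, return_alpha=True)
        np.testing.assert_allclose(alpha, 0.5, atol=1e-7)
        np.testing.assert_allclose(out, h / 2, atol=1e-6)

    def test_matches_straight_line_chain(self, rng):
        h = rng.normal(size=(2, 2, 2))
        g = rng.normal(size=(2, 2, 3))
        spec = AttentionGateSpec(intermediate_channels=2)
        w = init_attention_gate_weights(rng, 2, 3, spec)
        w["b_hg"] = rng.normal(size=2).astype(np.float32)
        w["b_int"] = rng.normal(size=2).astype(np.float32)
        w["b_k"] = rng.normal(size=1).astype(np.float32)
        out = attention_gate(h, g, spec, w)
        ref = oracles.attention_gate_loop(h, g, w)
        assert np.abs(out - ref).max() <= 1e-5

    def test_never_amplifies(self, rng):
        h = rng.normal(size=(5, 5, 4))
        g = rng.normal(size=(5, 5, 4))
        spec = AttentionGateSpec(intermediate_channels=3)
        w = init_attention_gate_weights(rng, 4, 4, spec)
        out = attention_gate(h, g, spec, w)
        assert np.all(np.abs(out) <= np.abs(h) + 1e-7)

    def test_spatial_mismatch_rejected(self, rng):
        spec = AttentionGateSpec(intermediate_channels=1)
        w = init_attention_gate_weights(rng, 1, 1, spec)
        with pytest.raises(ValueError, match="spatial"):
            attention_gate(np.zeros((4, 4, 1)), np.zeros((2, 2, 1)), spec, w)
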