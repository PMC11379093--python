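"""Equation-level behaviour of the ACB, PSCA and DFSM attention blocks:
closed-form degenerate cases, parameter sharing, and agreement with the
explicit-loop oracles."""

import numpy as np
import pytest

from choroidseg import ACB, DFSM, PSCA, acb_param_count
from choroidseg.nn import Tensor, conv2d, zero_learnable_weights
from oracles import acb_loop, dfsm_loop, psca_loop


class TestACB:
    def test_zero_kernel_gives_zero_output(self, rng):
        acb = ACB(3, 3, k=3, rng=rng)
        zero_learnable_weights(acb)
        x = Tensor(rng.normal(size=(1, 3, 6, 6)))
        assert np.all(acb(x).data == 0.0)

    def test_delta_kernel_triples_interior(self):
        """A centre-tap identity kernel passes x through each of the three
        branches, so the interior of the output is 3·x."""
        acb = ACB(1, 1, k=3)
        acb.weight.data[...] = 0.0
        acb.weight.data[0, 0, 1, 1] = 1.0
        acb.bias.data[...] = 0.0
        x = Tensor(np.ones((1, 1, 5, 5)))
        out = acb(x).data
        assert np.allclose(out[0, 0, 1:-1, 1:-1], 3.0)

    def test_matches_loop_oracle(self, rng):
        acb = ACB(3, 5, k=3, rng=rng)
        x = rng.normal(size=(1, 3, 8, 8))
        expected = acb_loop(x, acb.weight.data, acb.bias.data)
        assert np.abs(acb(Tensor(x)).data - expected).max() < 1e-6

    def test_linearity_without_bias(self, rng):
        acb = ACB(2, 2, k=3, bias=False, rng=rng)
        x = rng.normal(size=(1, 2, 6, 6))
        y = rng.normal(size=(1, 2, 6, 6))
        lhs = acb(Tensor(2.0 * x + 3.0 * y)).data
        rhs = 2.0 * acb(Tensor(x)).data + 3.0 * acb(Tensor(y)).data
        assert np.abs(lhs - rhs).max() < 1e-9

    @pytest.mark.parametrize(
        "c_in, c_out, k, expected",
        [(4, 4, 3, 148), (1, 1, 7, 50), (8, 1, 7, 8 * 49 + 1)],
    )
    def test_param_count_formula(self, c_in, c_out, k, expected):
        assert acb_param_count(c_in, c_out, k) == expected

    @pytest.mark.parametrize("c_in, c_out, k", [(4, 4, 3), (8, 1, 7)])
    def test_param_count_equals_plain_square_conv(self, rng, c_in, c_out, k):
        acb = ACB(c_in, c_out, k=k, rng=rng)
        assert acb.num_parameters() == acb_param_count(c_in, c_out, k)
        assert acb.num_parameters() == c_out * c_in * k * k + c_out

    def test_central_row_perturbation_moves_asymmetric_branch(self, rng):
        """The 1×k branch is a view of the square kernel's central row:
        perturbing that row must change its output; perturbing a corner tap
        must not."""
        acb = ACB(2, 2, k=3, rng=rng)
        x = Tensor(rng.normal(size=(1, 2, 6, 6)))
        c = acb.k // 2

        def row_branch():
            return conv2d(x, acb.weight[:, :, c : c + 1, :], padding=(0, c)).data

        base = row_branch()
        acb.weight.data[0, 0, c, 0] += 0.5  # central row
        assert np.abs(row_branch() - base).max() > 1e-6
        shifted = row_branch()
        acb.weight.data[0, 0, 0, 0] += 0.5  # corner: not in the row view
        assert np.array_equal(row_branch(), shifted)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            ACB(2, 2, k=4)
        with pytest.raises(ValueError):
            acb_param_count(2, 2, 4)

    def test_channel_mismatch_rejected(self, rng):
        acb = ACB(3, 3, rng=rng)
        with pytest.raises(ValueError, match="channels"):
            acb(Tensor(np.zeros((1, 4, 5, 5))))


class TestPSCA:
    def test_zero_weights_give_three_halves_input(self, rng):
        """With every conv zeroed the fused logits are 0, the sigmoid gate
        is 1/2 everywhere, and the residual makes out = 1.5·x."""
        psca = PSCA(6, ratio=2, rng=rng)
        zero_learnable_weights(psca)
        x = rng.normal(size=(2, 6, 5, 5))
        out = psca(Tensor(x)).data
        assert np.abs(out - 1.5 * x).max() < 1e-12

    def test_gate_lies_strictly_inside_unit_interval(self, rng):
        psca = PSCA(4, ratio=2, rng=rng)
        x = rng.uniform(0.5, 1.5, size=(1, 4, 6, 6))  # positive input
        out = psca(Tensor(x)).data
        gate = (out - x) / x
        assert np.all(gate > 0.0) and np.all(gate < 1.0)

    def test_matches_loop_oracle(self, rng):
        psca = PSCA(16, ratio=16, rng=rng)
        x = rng.normal(size=(1, 16, 8, 8))
        assert np.abs(psca(Tensor(x)).data - psca_loop(x, psca)).max() < 1e-5

    def test_translation_consistency_in_interior(self, rng):
        """All PSCA paths are convolutional + pointwise, so shifting the
        input one pixel shifts the output one pixel away from borders."""
        psca = PSCA(3, ratio=2, rng=rng)
        x = rng.normal(size=(1, 3, 16, 48))
        xs = np.roll(x, 1, axis=3)
        out = psca(Tensor(x)).data
        outs = psca(Tensor(xs)).data
        # margin 15 covers the 13-pixel receptive field of the 7x7 pair
        assert np.abs(
            np.roll(out, 1, axis=3)[:, :, :, 15:-15] - outs[:, :, :, 15:-15]
        ).max() < 1e-8

    def test_depthwise_paths_use_one_filter_per_channel(self, rng):
        psca = PSCA(8, rng=rng)
        assert psca.point_path.groups == 8
        assert psca.channel_path.groups == 8
        assert psca.dw7_a.groups == 8
        assert psca.channel_path.weight.shape == (8, 1, 3, 3)

    def test_channel_mismatch_rejected(self, rng):
        psca = PSCA(4, rng=rng)
        with pytest.raises(ValueError, match="channels"):
            psca(Tensor(np.zeros((1, 5, 4, 4))))


class TestDFSM:
    def test_zero_weight_cascade_vanishes_through_out_conv(self, rng):
        dfsm = DFSM(6, 6, ratio=2, rng=rng)
        zero_learnable_weights(dfsm)
        x = rng.normal(size=(1, 6, 5, 5))
        assert np.all(dfsm(Tensor(x)).data == 0.0)

    def test_zero_attention_weights_scale_input_by_three_quarters(self, rng):
        """With zeroed attention weights every gate is 1/2, so the merged
        features are 0.25·x + 0.5·x; an identity output projection then
        exposes 0.75·x directly."""
        dfsm = DFSM(4, 4, ratio=2, rng=rng)
        zero_learnable_weights(dfsm)
        dfsm.out_conv.weight.data[...] = np.eye(4)[:, :, None, None]
        x = rng.normal(size=(1, 4, 5, 5))
        out = dfsm(Tensor(x)).data
        assert np.abs(out - 0.75 * x).max() < 1e-12

    def test_attention_maps_lie_strictly_inside_unit_interval(self, rng):
        dfsm = DFSM(8, 8, rng=rng)
        x = rng.normal(size=(1, 8, 6, 6))
        from scipy.special import expit

        gap = x.mean(axis=(2, 3))
        h = np.maximum(gap @ dfsm.fc1.weight.data + dfsm.fc1.bias.data, 0)
        a_c = expit(h @ dfsm.fc2.weight.data + dfsm.fc2.bias.data)
        a_p = expit(
            (dfsm.point_conv(Tensor(x)).data)
        )
        for a in (a_c, a_p):
            assert np.all(a > 0) and np.all(a < 1)

    def test_matches_loop_oracle(self, rng):
        dfsm = DFSM(16, 8, ratio=16, rng=rng)
        x = rng.normal(size=(1, 16, 8, 8))
        assert np.abs(dfsm(Tensor(x)).data - dfsm_loop(x, dfsm)).max() < 1e-5

    def test_output_channels_follow_configuration(self, rng):
        dfsm = DFSM(12, 4, rng=rng)
        out = dfsm(Tensor(np.zeros((2, 12, 6, 6))))
        assert out.shape == (2, 4, 6, 6)

    def test_spatial_path_collapses_to_single_channel_map(self, rng):
        dfsm = DFSM(16, 16, ratio=16, rng=rng)
        assert dfsm.spatial_acb_1.weight.shape[0] == 1  # ceil(16/16)
        assert dfsm.spatial_acb_2.weight.shape[0] == 1

    def test_finite_output_for_finite_input(self, rng):
        for block in (PSCA(4, rng=rng), DFSM(4, 4, rng=rng), ACB(4, 4, rng=rng)):
            out = block(Tensor(rng.normal(size=(1, 4, 6, 6)) * 100.0)).data
            assert np.isfinite(out).all()
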