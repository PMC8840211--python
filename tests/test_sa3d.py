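"""Shuffle-attention semantics: grouping, gating, shuffling, composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rppgnet.autograd import Tensor
from rppgnet.sa3d import (
    InvalidGroupingError,
    ShuffleAttention3D,
    channel_branch,
    channel_shuffle,
    effective_groups,
    global_avg_pool,
    group_split,
    sa_block,
    spatial_branch,
)


def _sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


class TestGroupSplit:
    def test_two_groups_of_four_channels(self, rng):
        x = rng.standard_normal((4, 2, 2, 2))
        groups = group_split(x, 2)
        assert len(groups) == 2
        np.testing.assert_array_equal(groups[0][0], x[0:1])
        np.testing.assert_array_equal(groups[0][1], x[1:2])
        np.testing.assert_array_equal(groups[1][0], x[2:3])
        np.testing.assert_array_equal(groups[1][1], x[3:4])

    def test_single_group_halves_channels(self, rng):
        x = rng.standard_normal((6, 2, 2, 2))
        (xk1, xk2), = group_split(x, 1)
        np.testing.assert_array_equal(xk1, x[:3])
        np.testing.assert_array_equal(xk2, x[3:])

    def test_round_trip_reassembly_is_exact(self, rng):
        x = rng.standard_normal((16, 3, 2, 2))
        parts = [p for pair in group_split(x, 8) for p in pair]
        np.testing.assert_array_equal(np.concatenate(parts, axis=0), x)

    @pytest.mark.parametrize("C,G", [(4, 3), (4, 4), (2, 2)])
    def test_invalid_grouping_rejected(self, rng, C, G):
        with pytest.raises(InvalidGroupingError):
            group_split(rng.standard_normal((C, 2, 2, 2)), G)


class TestBranches:
    def test_gap_constant_volume(self):
        x = np.full((3, 2, 2, 2), 3.5)
        np.testing.assert_allclose(global_avg_pool(x), [3.5, 3.5, 3.5])

    def test_gap_single_voxel_identity(self):
        x = np.array([[[[2.0]]], [[[-1.0]]]])
        np.testing.assert_allclose(global_avg_pool(x), [2.0, -1.0])

    def test_gap_brute_force_sum(self):
        x = (np.arange(16, dtype=float) + 1).reshape(2, 2, 2, 2)
        expected = [sum(range(1, 9)) / 8.0, sum(range(9, 17)) / 8.0]
        np.testing.assert_allclose(global_avg_pool(x), expected)

    def test_channel_branch_zero_params_halves_input(self, rng):
        x = rng.standard_normal((3, 2, 2, 2))
        out = channel_branch(x, np.zeros(3), np.zeros(3))
        np.testing.assert_allclose(out, 0.5 * x)

    def test_channel_branch_saturated_gate_is_identity(self, rng):
        x = rng.standard_normal((2, 2, 2, 2))
        out = channel_branch(x, np.zeros(2), np.full(2, 50.0))
        np.testing.assert_allclose(out, x, rtol=1e-12)

    def test_channel_branch_scalar_oracle(self, rng):
        x = rng.standard_normal((1, 2, 2, 2))
        out = channel_branch(x, np.ones(1), np.zeros(1))
        np.testing.assert_allclose(out, _sigmoid(x.mean()) * x)

    def test_spatial_branch_constant_input_gates_by_bias(self):
        x = np.full((2, 2, 2, 2), 7.0)
        b2 = np.array([0.3, -0.4])
        out = spatial_branch(x, np.ones(2), b2)
        np.testing.assert_allclose(out, _sigmoid(b2)[:, None, None, None] * x)

    def test_spatial_branch_zero_weight_ignores_values(self, rng):
        x = rng.standard_normal((2, 3, 2, 2))
        out = spatial_branch(x, np.zeros(2), np.full(2, 0.7))
        np.testing.assert_allclose(out, _sigmoid(0.7) * x)

    def test_spatial_branch_scalar_oracle(self, rng):
        x = rng.standard_normal((1, 2, 2, 2))
        gn = (x - x.mean()) / np.sqrt(x.var() + 1e-5)
        np.testing.assert_allclose(
            spatial_branch(x, np.ones(1), np.zeros(1)), _sigmoid(gn) * x
        )

    def test_parameter_length_mismatch_rejected(self, rng):
        x = rng.standard_normal((3, 2, 2, 2))
        with pytest.raises(ValueError, match="shape"):
            channel_branch(x, np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError, match="shape"):
            spatial_branch(x, np.zeros(4), np.zeros(4))


class TestChannelShuffle:
    def test_enumerated_permutation(self):
        x = np.arange(4.0).reshape(4, 1, 1, 1)
        out = channel_shuffle(x, 2)[:, 0, 0, 0]
        np.testing.assert_array_equal(out, [0, 2, 1, 3])

    @pytest.mark.parametrize("G", [1, 6])
    def test_trivial_groupings_are_identity(self, rng, G):
        x = rng.standard_normal((6, 2, 2, 2))
        np.testing.assert_array_equal(channel_shuffle(x, G), x)

    def test_swapped_factors_invert(self, rng):
        x = rng.standard_normal((12, 2, 2, 2))
        np.testing.assert_array_equal(channel_shuffle(channel_shuffle(x, 3), 4), x)


class TestSABlock:
    @settings(max_examples=25, deadline=None)
    @given(
        G=st.integers(1, 4),
        half=st.integers(1, 3),
        T=st.integers(1, 4),
        H=st.integers(1, 4),
        W=st.integers(1, 4),
        seed=st.integers(0, 2**16),
    )
    def test_shape_preserved_for_valid_configs(self, G, half, T, H, W, seed):
        C = 2 * G * half
        x = np.random.default_rng(seed).standard_normal((C, T, H, W))
        params = [np.random.default_rng(seed + 1).standard_normal(C // 2)
                  for _ in range(4)]
        out = sa_block(x, G, *params)
        assert out.shape == x.shape

    def test_zero_input_gives_zero_output(self, rng):
        x = np.zeros((8, 2, 2, 2))
        out = sa_block(x, 2, *(rng.standard_normal(4) for _ in range(4)))
        np.testing.assert_array_equal(out, 0.0)

    def test_gates_bound_output_by_input(self, rng):
        x = rng.standard_normal((8, 3, 2, 2))
        out = sa_block(x, 2, *(rng.standard_normal(4) for _ in range(4)))
        # undo the shuffle to compare elementwise
        unshuffled = channel_shuffle(out, 4)
        assert np.all(np.abs(unshuffled) <= np.abs(x) + 1e-12)

    def test_composition_equals_components(self, rng):
        x = rng.standard_normal((4, 2, 3, 3))
        w1, b1, w2, b2 = (rng.standard_normal(2) for _ in range(4))
        expected_parts = []
        for k, (xk1, xk2) in enumerate(group_split(x, 2)):
            expected_parts.append(channel_branch(xk1, w1[k : k + 1], b1[k : k + 1]))
            expected_parts.append(spatial_branch(xk2, w2[k : k + 1], b2[k : k + 1]))
        expected = channel_shuffle(np.concatenate(expected_parts), 2)
        np.testing.assert_allclose(sa_block(x, 2, w1, b1, w2, b2), expected)

    def test_neutral_params_give_half_permuted_input(self, rng):
        """W=0, b=0 in both branches: every gate is exactly 1/2."""
        x = rng.standard_normal((8, 2, 2, 2))
        zero = np.zeros(4)
        out = sa_block(x, 2, zero, zero, zero, zero)
        np.testing.assert_allclose(out, 0.5 * channel_shuffle(x, 2), rtol=1e-12)


class TestShuffleAttention3DModule:
    def test_matches_functional_pipeline(self, rng):
        x = rng.standard_normal((1, 8, 2, 3, 3)).astype(np.float64)
        mod = ShuffleAttention3D(8, groups=2)
        w1 = rng.standard_normal(4)
        b1 = rng.standard_normal(4)
        w2 = rng.standard_normal(4)
        b2 = rng.standard_normal(4)
        mod.w1.data, mod.b1.data = w1.copy(), b1.copy()
        mod.w2.data, mod.b2.data = w2.copy(), b2.copy()
        out = mod(Tensor(x)).data[0]
        expected = sa_block(x[0], 2, w1, b1, w2, b2)
        np.testing.assert_allclose(out, expected, rtol=1e-6)

    def test_group_clamping_for_thin_layers(self):
        assert effective_groups(16, 4) == 4
        assert effective_groups(6, 4) == 3
        assert effective_groups(2, 4) == 1
        mod = ShuffleAttention3D(6, groups=4)
        assert mod.groups == 3

    def test_gradient_flow(self, rng):
        from rppgnet.autograd import gradcheck

        mod = ShuffleAttention3D(4, groups=1)
        x = Tensor(rng.standard_normal((1, 4, 2, 2, 2)), requires_grad=True)
        assert gradcheck(lambda a: (mod(a) ** 2).sum(), [x])
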