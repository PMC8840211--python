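"""Architecture assembly, shape contracts, and complexity accounting."""

import numpy as np
import pytest

from rppgnet.autograd import Tensor, no_grad
from rppgnet.backbone import (
    ConvComplexity,
    DCBlock,
    EBlock,
    LayerSpec,
    NetworkSpec,
    RPPGNet,
    default_network_spec,
    dw_sep_macs,
    h_swish,
    load_checkpoint,
    profile,
    relu6,
    save_checkpoint,
    std_conv_macs,
)
from rppgnet.nn import TemporalConvTransposeDW


class TestNonlinearities:
    def test_h_swish_breakpoints(self):
        assert h_swish(0.0) == 0.0
        assert h_swish(3.0) == 3.0
        assert h_swish(-3.0) == 0.0
        assert h_swish(10.0) == 10.0          # saturated gate
        assert h_swish(1.0) == pytest.approx(2.0 / 3.0)

    def test_relu6_clamps(self):
        np.testing.assert_array_equal(relu6(np.array([-1.0, 3.0, 9.0])), [0.0, 3.0, 6.0])


def _loop_nest_std_macs(c: ConvComplexity) -> int:
    """Count multiplications of a dense convolution by explicit enumeration."""
    count = 0
    for _n in range(c.N):
        for _t in range(c.T):
            for _gy in range(c.Dg):
                for _gx in range(c.Dg):
                    count += c.Dk**3 * c.M  # one multiply per kernel tap x input channel
    return count


class TestComplexityFormulas:
    def test_std_macs_against_loop_nest(self):
        c = ConvComplexity(Df=8, Dg=4, Dk=3, M=2, N=4, T=2)
        assert std_conv_macs(c) == _loop_nest_std_macs(c) == 6912

    def test_std_macs_degenerate_unit(self):
        assert std_conv_macs(ConvComplexity(1, 1, 1, 1, 1, 1)) == 1

    def test_std_macs_linear_in_time(self):
        c1 = ConvComplexity(8, 4, 3, 2, 4, 2)
        c2 = ConvComplexity(8, 4, 3, 2, 4, 4)
        assert std_conv_macs(c2) == 2 * std_conv_macs(c1)

    def test_dw_sep_macs_from_parts(self):
        c = ConvComplexity(Df=8, Dg=4, Dk=3, M=2, N=4, T=2)
        depthwise = 27 * 16 * 2 * 2   # Dk^3 Dg^2 M T
        pointwise = 16 * 2 * 4 * 2    # Dg^2 M N T
        assert depthwise == 1728 and pointwise == 256
        assert dw_sep_macs(c) == depthwise + pointwise == 1984
        # consistency with the ratio identity on the same shapes
        assert dw_sep_macs(c) / std_conv_macs(c) == pytest.approx(1 / 4 + 1 / 27)

    def test_dw_sep_collapses_for_unit_kernel(self):
        c = ConvComplexity(Df=4, Dg=4, Dk=1, M=3, N=5, T=2)
        assert dw_sep_macs(c) == 16 * 3 * 2 * (1 + 5)

    @pytest.mark.parametrize("dk", [1, 3, 5])
    @pytest.mark.parametrize("n", [1, 8, 16, 64])
    def test_separable_ratio_closed_form(self, dk, n):
        c = ConvComplexity(Df=8, Dg=8, Dk=dk, M=4, N=n, T=4)
        ratio = dw_sep_macs(c) / std_conv_macs(c)
        assert ratio == pytest.approx(1.0 / n + 1.0 / dk**3, rel=1e-12)

    def test_separable_always_cheaper_when_nontrivial(self):
        for dk in (3, 5):
            for n in (2, 8, 32):
                c = ConvComplexity(8, 8, dk, 4, n, 4)
                assert dw_sep_macs(c) < std_conv_macs(c)


class TestProfiler:
    def test_single_conv_layer_closed_form(self):
        spec = NetworkSpec(
            layers=[LayerSpec("stem-conv", kernel=3, out=16, stride=(1, 1, 1))],
            in_channels=3,
        )
        macs, params, table = profile(spec, (3, 8, 16, 16))
        assert macs == std_conv_macs(ConvComplexity(16, 16, 3, 3, 16, 8))
        assert params == 27 * 3 * 16 + 2 * 16  # weights + BN affine

    def test_empty_network(self):
        macs, params, table = profile(NetworkSpec(layers=[]), (3, 8, 32, 32))
        assert (macs, params, table) == (0, 0, [])

    def test_param_total_matches_instantiated_model(self):
        spec = default_network_spec()
        _, params, _ = profile(spec, (3, 128, 128, 128))
        assert params == RPPGNet(spec, seed=0).num_parameters()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            LayerSpec("mystery-op")


# printed architecture rows as (H, W, T, C) input per layer
TABLE_INPUTS = [
    (128, 128, 3), (64, 128, 16), (32, 128, 16), (16, 128, 24), (16, 128, 24),
    (8, 64, 40), (8, 64, 40), (8, 64, 40), (8, 64, 48), (8, 64, 48),
    (4, 32, 96), (4, 32, 96), (4, 32, 96), (4, 32, 576), (4, 64, 288),
    (4, 128, 144), (4, 128, 64), (1, 128, 64),
]


class TestNetworkSpec:
    def test_shape_propagation_reproduces_architecture_table(self):
        spec = default_network_spec()
        shapes = spec.propagate_shapes((3, 128, 128, 128))
        assert len(shapes) == len(TABLE_INPUTS)
        for (sin, _), (hw, t, c) in zip(shapes, TABLE_INPUTS):
            assert sin == (c, t, hw, hw)
        # final output: one channel, full temporal length, 1x1 spatial
        assert shapes[-1][1] == (1, 128, 1, 1)

    def test_encoder_decoder_temporal_path(self):
        """T halves twice in the encoder (128-64-32), doubles back to 128."""
        spec = default_network_spec()
        ts = [s[0][1] for s in spec.propagate_shapes((3, 128, 128, 128))]
        assert min(ts) == 32
        assert ts[-1] == 128

    def test_nonlinearity_placement(self):
        """ReLU6 in the early blocks, h-swish from the first 5-kernel block on."""
        spec = default_network_spec()
        nls = [l.nl for l in spec.layers if l.kind in ("stem-conv", "eblock")]
        assert nls[:4] == ["relu6"] * 4
        assert all(nl == "hswish" for nl in nls[4:])

    def test_eblock_strided_rows(self):
        spec = default_network_spec()
        shapes = spec.propagate_shapes((3, 128, 128, 128))
        # second row: 64^2 x 128 x 16 input, stride (1,2,2) -> 32^2 x 128 x 16
        assert shapes[1] == ((16, 128, 64, 64), (16, 128, 32, 32))
        # fifth row: 16^2 x 128 x 24, kernel 5, stride (2,2,2) -> 8^2 x 64 x 40
        assert shapes[4] == ((24, 128, 16, 16), (40, 64, 8, 8))

    def test_dcblock_rows_double_time(self):
        spec = default_network_spec()
        shapes = spec.propagate_shapes((3, 128, 128, 128))
        assert shapes[13] == ((576, 32, 4, 4), (288, 64, 4, 4))
        assert shapes[14] == ((288, 64, 4, 4), (144, 128, 4, 4))

    def test_text_round_trip(self):
        spec = default_network_spec()
        again = NetworkSpec.from_text(spec.to_text())
        assert again.layers == spec.layers
        assert again.in_channels == spec.in_channels
        assert again.gru_kernel == spec.gru_kernel

    def test_input_contract_errors_name_offending_dimension(self):
        spec = default_network_spec()
        with pytest.raises(ValueError, match="temporal"):
            spec.validate_input((3, 126, 128, 128))
        with pytest.raises(ValueError, match="height"):
            spec.validate_input((3, 128, 100, 128))


class TestBlocks:
    def test_eblock_pure_skip_when_weights_zero(self, rng):
        spec = LayerSpec("eblock", 3, 8, 4, (1, 1, 1), False, "relu6")
        block = EBlock(4, spec, sa_groups=1, rng=np.random.default_rng(0))
        for name, p in block.named_parameters():
            if "weight" in name and p.ndim == 5:
                p.data[:] = 0.0
        x = Tensor(rng.standard_normal((1, 4, 4, 6, 6)).astype(np.float32))
        with no_grad():
            out = block(x)
        np.testing.assert_allclose(out.data, x.data, atol=1e-6)

    def test_dcblock_zero_weights_give_zero_no_skip(self, rng):
        spec = LayerSpec("dcblock", 4, 0, 3, (2, 1, 1), False, "hswish")
        block = DCBlock(6, spec, rng=np.random.default_rng(0))
        for name, p in block.named_parameters():
            if p.ndim == 5:
                p.data[:] = 0.0
        x = Tensor(rng.standard_normal((1, 6, 4, 3, 3)).astype(np.float32))
        with no_grad():
            out = block(x)
        assert out.shape == (1, 3, 8, 3, 3)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-7)

    def test_temporal_transpose_matches_brute_force(self, rng):
        """Depth-wise temporal transposed conv vs an explicit scatter oracle."""
        mod = TemporalConvTransposeDW(2, 4, 2, 1, bias=False,
                                      rng=np.random.default_rng(3))
        x = rng.standard_normal((1, 2, 5, 1, 1)).astype(np.float64)
        w = mod.weight.data.astype(np.float64)
        expected = np.zeros((1, 2, 12, 1, 1))
        for c in range(2):
            for i in range(5):
                for j in range(4):
                    o = 2 * i + j - 1  # stride 2, padding 1
                    if 0 <= o < 12:
                        expected[0, c, o] += x[0, c, i] * w[c, 0, j]
        expected = expected[:, :, :10]  # trimmed to 2x input length
        with no_grad():
            out = mod(Tensor(x)).data
        np.testing.assert_allclose(out, expected, rtol=1e-5)


@pytest.fixture(scope="module")
def model():
    return RPPGNet(seed=0)


class TestForward:

    def test_small_input_shapes_follow_propagation(self, model):
        """A reduced 3x8x32x32 volume walks the same closed-form shape chain."""
        x = np.random.default_rng(0).standard_normal((1, 3, 8, 32, 32)).astype(np.float32)
        expected = model.spec.propagate_shapes((3, 8, 32, 32))
        seen = {}
        with no_grad():
            out = model(Tensor(x), shape_hook=lambda i, s: seen.update({i: s}))
        for i, (_, sout) in enumerate(expected):
            assert seen[i] == (1, *sout), f"layer {i}"
        assert out.shape == (1, 8)

    def test_forward_is_deterministic(self, model):
        x = np.random.default_rng(1).standard_normal((1, 3, 8, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(model.infer(x), model.infer(x))

    def test_invalid_temporal_length_rejected(self, model):
        x = np.zeros((1, 3, 6, 32, 32), dtype=np.float32)
        with pytest.raises(ValueError, match="temporal"):
            model.infer(x)

    def test_checkpoint_round_trip(self, model, tmp_path):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model)
        again = load_checkpoint(path)
        x = np.random.default_rng(2).standard_normal((1, 3, 8, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(model.infer(x), again.infer(x))
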