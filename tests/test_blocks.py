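"""Contract and oracle tests for the network building blocks.

Block interfaces are channel-first (N, C, H, W).
"""

import numpy as np
import pytest

from mbsnet import autograd as ag
from mbsnet.blocks import (FCFB, PRM, ConvBNAct, ConvSpec, DilatedBlock,
                           DilationSpec, SEBlock, SpatialAttention, UpConv)


def _zero_all(module):
    for p in module.parameters():
        p.data[...] = 0.0
    # normalization gains must stay at 1 to be no-ops on zero inputs is not
    # needed: BN(0)=offset=0; keep everything zero as the contract states.


def direct_conv(x, w, dilation):
    """Nested-loop convolution oracle with zero padding, stride 1."""
    n, cin, h, wd = x.shape
    cout, _, k, _ = w.shape
    pad = dilation * (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((n, cout, h, wd), dtype=np.float64)
    for b in range(n):
        for o in range(cout):
            for y in range(h):
                for z in range(wd):
                    acc = 0.0
                    for c in range(cin):
                        for i in range(k):
                            for j in range(k):
                                acc += (w[o, c, i, j]
                                        * xp[b, c, y + i * dilation, z + j * dilation])
                    out[b, o, y, z] = acc
    return out


class TestConvBNAct:
    def test_shape_contract_full_resolution(self, rng):
        block = ConvBNAct(ConvSpec(3, 16, kernel=3), rng=rng)
        out = block(rng.normal(size=(1, 3, 320, 320)).astype(np.float32))
        assert out.shape == (1, 16, 320, 320)

    @pytest.mark.parametrize("kernel,dilation", [(1, 1), (3, 1), (3, 2), (3, 4)])
    def test_padding_preserves_spatial_dims(self, rng, kernel, dilation):
        spec = ConvSpec(2, 5, kernel=kernel, dilation=dilation)
        assert spec.padding == dilation * (kernel - 1) // 2
        block = ConvBNAct(spec, rng=rng)
        out = block(rng.normal(size=(2, 2, 5, 5)).astype(np.float32))
        assert out.shape == (2, 5, 5, 5)

    def test_all_ones_kernel_center_value(self):
        block = ConvBNAct(ConvSpec(1, 1, kernel=3, use_norm=False,
                                   activation="none"))
        block.conv.weight.data[...] = 1.0
        block.conv.bias.data[...] = 0.0
        out = block(np.ones((1, 1, 5, 5), dtype=np.float32))
        assert out.data[0, 0, 2, 2] == pytest.approx(9.0)

    @pytest.mark.parametrize("kernel,dilation", [(1, 1), (3, 1), (3, 2), (3, 4)])
    def test_agrees_with_nested_loop_oracle(self, rng, kernel, dilation):
        x = rng.normal(size=(1, 3, 5, 5)).astype(np.float32)
        block = ConvBNAct(ConvSpec(3, 4, kernel=kernel, dilation=dilation,
                                   use_norm=False, activation="none"), rng=rng)
        block.conv.bias.data[...] = 0.0
        expected = direct_conv(x, block.conv.weight.data.astype(np.float64),
                               dilation)
        np.testing.assert_allclose(block(x).data, expected, atol=1e-5)

    def test_channel_mismatch_raises_named_error(self, rng):
        block = ConvBNAct(ConvSpec(4, 8), rng=rng)
        with pytest.raises(ValueError, match="expected 4.*received 3"):
            block(np.zeros((1, 3, 8, 8), dtype=np.float32))

    def test_batch_vs_running_statistics(self, rng):
        block = ConvBNAct(ConvSpec(2, 4), rng=rng)
        x = rng.normal(size=(4, 2, 8, 8)).astype(np.float32)
        block.train()
        out_train = block(x).data
        block.eval()
        out_eval = block(x).data
        assert not np.allclose(out_train, out_eval)


class TestDilationSpec:
    def test_multi_grid_rates(self):
        spec = DilationSpec(rate_multiplier=2, multi_grid=(1, 2, 4))
        assert spec.rates == (2, 4, 8)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            DilationSpec(rate_multiplier=0)
        with pytest.raises(ValueError):
            DilatedBlock(4, 4, rate=0)

    def test_dilated_conv_receptive_field_span(self):
        # a 3x3 kernel at dilation 4 spans k + (k-1)(d-1) = 9 pixels
        w = ag.Tensor(np.ones((1, 1, 3, 3), dtype=np.float32))
        impulse = np.zeros((1, 17, 17, 1), dtype=np.float32)
        impulse[0, 8, 8, 0] = 1.0
        response = ag.conv2d(ag.Tensor(impulse), w, dilation=4).data[0, :, :, 0]
        rows = np.nonzero(response.any(axis=1))[0]
        assert rows.max() - rows.min() + 1 == 9


class TestDilatedBlock:
    def test_shape_contract(self, rng):
        block = DilatedBlock(16, 32, rate=4, rng=rng)
        out = block(rng.normal(size=(1, 16, 160, 160)).astype(np.float32))
        assert out.shape == (1, 32, 160, 160)


class TestPRM:
    def test_residual_shape(self, rng):
        block = PRM(16, rng=rng)
        out = block(rng.normal(size=(1, 16, 64, 64)).astype(np.float32))
        assert out.shape == (1, 16, 64, 64)

    def test_zero_weights_exact_identity(self, rng):
        block = PRM(8, rng=rng)
        _zero_all(block)
        x = rng.normal(size=(2, 8, 16, 16)).astype(np.float32)
        out = block(x).data
        assert np.max(np.abs(out - x)) == 0.0

    def test_maxpool_path_window_oracle(self):
        ramp = np.arange(16, dtype=np.float32).reshape(1, 4, 4, 1)
        out = ag.maxpool3x3_s1(ag.Tensor(ramp)).data
        padded = np.pad(ramp, ((0, 0), (1, 1), (1, 1), (0, 0)),
                        constant_values=-np.inf)
        for i in range(4):
            for j in range(4):
                assert out[0, i, j, 0] == padded[0, i:i + 3, j:j + 3, 0].max()

    def test_non_finite_input_rejected(self, rng):
        block = PRM(4, rng=rng)
        bad = np.full((1, 4, 8, 8), np.nan, dtype=np.float32)
        with pytest.raises(ValueError, match="non-finite"):
            block(bad)


class TestSEBlock:
    def test_zero_weights_halve_input(self, rng):
        block = SEBlock(8, reduction=4, rng=rng)
        _zero_all(block)
        x = rng.normal(size=(1, 8, 6, 6)).astype(np.float32)
        np.testing.assert_allclose(block(x).data, 0.5 * x, atol=1e-7)

    def test_shape(self, rng):
        block = SEBlock(32, reduction=4, rng=rng)
        out = block(rng.normal(size=(1, 32, 40, 40)).astype(np.float32))
        assert out.shape == (1, 32, 40, 40)

    def test_hand_evaluated_gate(self):
        block = SEBlock(2, reduction=2)
        block.fc1.weight.data[...] = [[1.0, 0.0]]
        block.fc1.bias.data[...] = 0.0
        block.fc2.weight.data[...] = [[1.0], [0.0]]
        block.fc2.bias.data[...] = 0.0
        x = np.array([4.0, 0.0], dtype=np.float32).reshape(1, 2, 1, 1)
        # squeeze = (4, 0); hidden = relu(4) = 4; gates = sigmoid((4, 0))
        g0 = 1 / (1 + np.exp(-4.0))
        out = block(x).data[:, :, 0, 0]
        np.testing.assert_allclose(out, [[4.0 * g0, 0.0]], rtol=1e-6)

    def test_invalid_reduction_rejected(self):
        with pytest.raises(ValueError):
            SEBlock(4, reduction=8)
        with pytest.raises(ValueError):
            SEBlock(6, reduction=4)


class TestSpatialAttention:
    def test_residual_shape(self, rng):
        block = SpatialAttention(64, rng=rng)
        out = block(rng.normal(size=(1, 64, 80, 80)).astype(np.float32))
        assert out.shape == (1, 64, 80, 80)

    def test_attention_sums_to_one(self, rng):
        block = SpatialAttention(16, rng=rng)
        x = ag.nchw_to_nhwc(ag.Tensor(
            rng.normal(size=(3, 16, 8, 8)).astype(np.float32)))
        a = block.channel_attention(x).data
        np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-6)

    def test_unit_value_map_gives_unit_context(self, rng):
        block = SpatialAttention(8, rng=rng)
        block.value.weight.data[...] = 0.0
        block.value.bias.data[...] = 1.0            # V == 1 everywhere
        x = rng.normal(size=(1, 8, 6, 6)).astype(np.float32)
        out = block(x).data
        np.testing.assert_allclose(out, x + 1.0, atol=1e-6)

    def test_zero_value_weights_identity(self, rng):
        block = SpatialAttention(8, rng=rng)
        block.value.weight.data[...] = 0.0
        block.value.bias.data[...] = 0.0
        x = rng.normal(size=(1, 8, 6, 6)).astype(np.float32)
        assert np.max(np.abs(block(x).data - x)) == 0.0

    def test_zero_weights_exact_identity(self, rng):
        block = SpatialAttention(8, rng=rng)
        _zero_all(block)
        x = rng.normal(size=(2, 8, 12, 12)).astype(np.float32)
        assert np.max(np.abs(block(x).data - x)) == 0.0


class TestUpConv:
    def test_shape(self, rng):
        block = UpConv(128, 64, rng=rng)
        out = block(rng.normal(size=(1, 128, 40, 40)).astype(np.float32))
        assert out.shape == (1, 64, 80, 80)

    def test_constant_input_constant_output(self, rng):
        block = UpConv(4, 4, rng=rng)
        block.eval()
        # identity-like kernel: center tap only, so border padding is unused
        w = block.conv.conv.weight.data
        w[...] = 0.0
        for c in range(4):
            w[c, c, 1, 1] = 1.0
        out = block(np.full((1, 4, 8, 8), 3.0, dtype=np.float32)).data
        spread = out.max(axis=(2, 3)) - out.min(axis=(2, 3))
        np.testing.assert_allclose(spread, 0.0, atol=1e-5)

    def test_applying_twice_quadruples_dims(self, rng):
        a = UpConv(8, 8, rng=rng)
        b = UpConv(8, 8, rng=rng)
        out = b(a(rng.normal(size=(1, 8, 8, 8)).astype(np.float32)))
        assert out.shape == (1, 8, 32, 32)


class TestFCFB:
    def test_configured_channel_halving_contract(self, rng):
        block = FCFB(64, 32, rng=rng)
        y_g = rng.normal(size=(1, 64, 80, 80)).astype(np.float32)
        y_l = rng.normal(size=(1, 64, 80, 80)).astype(np.float32)
        o_g, o_l = block(y_g, y_l)
        assert o_g.shape == (1, 32, 160, 160)
        assert o_l.shape == (1, 32, 160, 160)

    def test_zero_crossing_conv_leaves_projected_upsample(self, rng):
        block = FCFB(4, 4, rng=rng)
        for p in block.upconv_l.parameters():
            p.data[...] = 0.0
        y_g = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        y_l = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        o_g, _ = block(y_g, y_l)
        proj = ag.upsample_bilinear2x(
            block.proj_g.forward_nhwc(ag.nchw_to_nhwc(ag.Tensor(y_g))))
        np.testing.assert_allclose(o_g.data, ag.nhwc_to_nchw(proj).data,
                                   atol=1e-6)

    def test_mismatched_streams_rejected(self, rng):
        block = FCFB(4, 4, rng=rng)
        with pytest.raises(ValueError, match="shapes differ"):
            block(np.zeros((1, 4, 8, 8), dtype=np.float32),
                  np.zeros((1, 4, 6, 6), dtype=np.float32))


class TestResidualBlockProperties:
    @pytest.mark.parametrize("hw", [16, 32, 64])
    def test_residual_blocks_preserve_randomized_shapes(self, rng, hw):
        x = rng.normal(size=(1, 8, hw, hw)).astype(np.float32)
        for block in (PRM(8, rng=rng), SpatialAttention(8, rng=rng)):
            assert block(x).shape == x.shape

    def test_gradients_reach_every_learnable_tensor(self, rng):
        blocks = {
            "prm": PRM(8, rng=rng),
            "dilated": DilatedBlock(8, 8, rate=2, rng=rng),
            "se": SEBlock(8, reduction=4, rng=rng),
            "sam": SpatialAttention(8, rng=rng),
            "upconv": UpConv(8, 8, rng=rng),
        }
        x = rng.normal(size=(2, 8, 8, 8)).astype(np.float32)
        target = rng.normal(size=(2, 8, 8, 8)).astype(np.float32)
        for name, block in blocks.items():
            out = block(x)
            if name == "upconv":
                loss = ag.tsum(ag.mul(out, ag.Tensor(np.ones(out.shape, np.float32))))
            else:
                loss = ag.tsum(ag.mul(ag.add(out, ag.Tensor(-target)),
                                      ag.add(out, ag.Tensor(-target))))
            loss.backward()
            for pname, p in block.named_parameters():
                assert p.grad is not None, f"{name}.{pname} got no gradient"
                assert np.any(p.grad != 0), f"{name}.{pname} gradient all zero"

    def test_fcfb_gradients_reach_every_tensor(self, rng):
        block = FCFB(4, 4, rng=rng)
        y_g = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        y_l = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        o_g, o_l = block(y_g, y_l)
        ag.tsum(ag.add(ag.mul(o_g, o_g), ag.mul(o_l, o_l))).backward()
        for pname, p in block.named_parameters():
            assert p.grad is not None and np.any(p.grad != 0), pname
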