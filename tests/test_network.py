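"""Architecture checks: shapes, channel plan, parameter count, attention."""

import numpy as np
import pytest

from attnseg.nn import autodiff as ad
from attnseg.nn.autodiff import Tensor
from attnseg.nn.layers import ConvBlock, DecoderBlock, SpatialAttentionBlock
from attnseg.nn.model import AttentionUNet, NetworkCfg

from oracles import conv2d_naive, pool_naive


def conv_block_params(f_in, f_out):
    """Closed-form parameter count of a triple-3x3-conv block."""
    return (9 * f_in * f_out + f_out) + 2 * (9 * f_out * f_out + f_out)


def attention_params(c):
    """1x1 gate conv (2c->2c) + 1x1 value conv (c->2c)."""
    return (2 * c * 2 * c + 2 * c) + (c * 2 * c + 2 * c)


def expected_total_params(c, in_ch=3, out_ch=1):
    """Closed-form sum over the whole layer plan at first-block width c."""
    enc = (
        conv_block_params(in_ch, c)
        + attention_params(c)
        + conv_block_params(2 * c, 2 * c)
        + conv_block_params(2 * c, 4 * c)
        + attention_params(4 * c)
        + conv_block_params(8 * c, 8 * c)
        + conv_block_params(8 * c, 16 * c)
    )
    dec = (
        conv_block_params(16 * c + 8 * c, 8 * c)
        + conv_block_params(8 * c + 4 * c, 4 * c)
        + conv_block_params(4 * c + 2 * c, 2 * c)
        + conv_block_params(2 * c + c, c)
    )
    head = 9 * c * out_ch + out_ch
    return enc + dec + head


class TestConvBlock:
    def test_channel_plan_3_to_16(self, rng):
        block = ConvBlock(3, 16, rng)
        y = block(Tensor(rng.random((1, 3, 8, 8))))
        assert y.data.shape == (1, 16, 8, 8)

    def test_zero_weights_give_zero_output(self, rng):
        block = ConvBlock(3, 4, rng)
        for conv in block.convs:
            conv.weight.data[:] = 0
            conv.bias.data[:] = 0
        y = block(Tensor(rng.random((1, 3, 8, 8))))
        np.testing.assert_array_equal(y.data, 0.0)

    def test_matches_naive_conv_relu_chain(self, rng):
        block = ConvBlock(2, 3, rng)
        x = rng.standard_normal((2, 4, 4))
        expected = x
        for i, conv in enumerate(block.convs):
            expected = conv2d_naive(expected, conv.weight.data, conv.bias.data)
            if i < 2:  # ReLU sits between convolutions, not after the last
                expected = np.maximum(expected, 0.0)
        y = block(Tensor(x[None])).data[0]
        np.testing.assert_allclose(y, expected, atol=1e-10)

    def test_residual_flag(self, rng):
        block = ConvBlock(4, 4, rng, residual=True)
        x = rng.standard_normal((1, 4, 4, 4))
        plain = ConvBlock(4, 4, rng, residual=False)
        for c_to, c_from in zip(plain.convs, block.convs):
            c_to.weight.data = c_from.weight.data.copy()
            c_to.bias.data = c_from.bias.data.copy()
        np.testing.assert_allclose(
            block(Tensor(x)).data, plain(Tensor(x)).data + x, atol=1e-12
        )


class TestSpatialAttentionBlock:
    def test_shape_halves_resolution_doubles_channels(self, rng):
        att = SpatialAttentionBlock(16, rng)
        y = att(Tensor(rng.random((1, 16, 32, 32))))
        assert y.data.shape == (1, 32, 16, 16)

    def test_zero_gate_weights_give_half_value_path(self, rng):
        att = SpatialAttentionBlock(4, rng)
        att.gate_conv.weight.data[:] = 0
        att.gate_conv.bias.data[:] = 0
        x = Tensor(rng.random((1, 4, 8, 8)))
        y = att(x)
        # sigmoid(0) = 0.5 everywhere -> output is exactly half the value path
        value = att.value_conv(ad.maxpool2d(x, att.pool))
        np.testing.assert_allclose(y.data, 0.5 * value.data, atol=1e-12)

    def test_gate_preactivation_matches_pooling_oracle(self, rng):
        att = SpatialAttentionBlock(2, rng)
        x = rng.standard_normal((2, 4, 4))
        pooled = np.concatenate(
            [pool_naive(x, 2, np.mean), pool_naive(x, 2, np.max)], axis=0
        )
        pre = conv2d_naive(pooled, att.gate_conv.weight.data, att.gate_conv.bias.data)
        gate = 1.0 / (1.0 + np.exp(-pre))
        value = conv2d_naive(
            pool_naive(x, 2, np.max), att.value_conv.weight.data, att.value_conv.bias.data
        )
        y = att(Tensor(x[None])).data[0]
        np.testing.assert_allclose(y, gate * value, atol=1e-10)

    def test_gate_values_strictly_in_unit_interval(self, rng):
        att = SpatialAttentionBlock(8, rng)
        att(Tensor(rng.standard_normal((2, 8, 16, 16))))
        assert np.all(att.last_gate_ > 0.0) and np.all(att.last_gate_ < 1.0)

    def test_channel_mismatch_raises(self, rng):
        att = SpatialAttentionBlock(8, rng)
        with pytest.raises(ValueError):
            att(Tensor(rng.random((1, 4, 8, 8))))


class TestDecoderBlock:
    def test_shape_arithmetic(self, rng):
        block = DecoderBlock(256 + 128, 128, up_factor=4, rng=rng)
        x = Tensor(rng.random((1, 256, 8, 8)))
        skip = Tensor(rng.random((1, 128, 32, 32)))
        assert block(x, skip).data.shape == (1, 128, 32, 32)

    def test_resolution_mismatch_raises(self, rng):
        block = DecoderBlock(8, 4, up_factor=2, rng=rng)
        with pytest.raises(ValueError, match="mismatch"):
            block(Tensor(rng.random((1, 4, 4, 4))), Tensor(rng.random((1, 4, 16, 16))))

    def test_zero_skip_ignored_by_masked_weights(self, rng):
        # zero the first conv's weights over the skip channels: output equals
        # a plain conv block applied to the upsampled features alone
        block = DecoderBlock(4 + 2, 3, up_factor=1, rng=rng)
        x = rng.standard_normal((1, 4, 4, 4))
        skip = np.zeros((1, 2, 4, 4))
        y_with = block(Tensor(x), Tensor(skip)).data
        block.block.convs[0].weight.data[:, 4:, :, :] = 0
        y_masked = block(Tensor(x), Tensor(skip)).data
        np.testing.assert_allclose(y_with, y_masked, atol=1e-12)


class TestAttentionUNet:
    @pytest.mark.parametrize("size", [64, 128])
    def test_output_spatial_dims_equal_input(self, size):
        model = AttentionUNet(NetworkCfg(in_channels=1, width_multiplier=0.125))
        x = np.random.default_rng(0).random((1, 1, size, size))
        y = model.predict_proba(x)
        assert y.shape == (1, 1, size, size)
        assert np.all((y > 0) & (y < 1))

    def test_encoder_resolutions_and_channels(self):
        model = AttentionUNet(NetworkCfg(in_channels=3, width_multiplier=1.0))
        x = Tensor(np.random.default_rng(1).random((1, 3, 512, 512)))
        with ad.no_grad():
            fp4, skips = model.encoder_forward(x)
        assert fp4.data.shape == (1, 128, 8, 8)
        assert [s.data.shape[1] for s in skips] == [16, 32, 64, 128]
        assert [s.data.shape[2] for s in skips] == [512, 256, 64, 32]
        assert len(skips) == 4

    def test_encoder_64_input_collapses_to_1x1(self):
        model = AttentionUNet(NetworkCfg(in_channels=3, width_multiplier=1.0))
        with ad.no_grad():
            fp4, _ = model.encoder_forward(
                Tensor(np.random.default_rng(1).random((1, 3, 64, 64)))
            )
        assert fp4.data.shape == (1, 128, 1, 1)

    def test_bottleneck_widens_128_to_256(self):
        model = AttentionUNet(NetworkCfg())
        with ad.no_grad():
            y = model.bottleneck(Tensor(np.random.default_rng(0).random((1, 128, 8, 8))))
        assert y.data.shape == (1, 256, 8, 8)

    def test_bottleneck_param_count_closed_form(self):
        model = AttentionUNet(NetworkCfg())
        expected = (9 * 128 * 256 + 256) + 2 * (9 * 256 * 256 + 256)
        assert sum(p.data.size for p in model.bottleneck.parameters()) == expected

    def test_indivisible_input_raises_with_message(self):
        model = AttentionUNet(NetworkCfg(in_channels=1, width_multiplier=0.125))
        with pytest.raises(ValueError, match="divisible by 64"):
            model.forward(np.zeros((1, 1, 60, 60)))

    @pytest.mark.parametrize("mult,in_ch,out_ch", [(1.0, 3, 1), (0.25, 1, 1), (0.5, 3, 3)])
    def test_total_param_count_matches_closed_form(self, mult, in_ch, out_ch):
        cfg = NetworkCfg(in_channels=in_ch, out_channels=out_ch, width_multiplier=mult)
        model = AttentionUNet(cfg)
        assert model.param_count() == expected_total_params(cfg.width(), in_ch, out_ch)

    def test_channel_progression_matches_plan(self):
        cfg = NetworkCfg()
        assert cfg.encoder_widths == [16, 32, 32, 64, 128, 128, 256]
        assert cfg.decoder_widths == [128, 64, 32, 16]
        rows = AttentionUNet(cfg).summary(512)
        enc = [r["out_channels"] for r in rows[:7]]
        dec = [r["out_channels"] for r in rows[7:11]]
        assert enc == [16, 32, 32, 64, 128, 128, 256]
        assert dec == [128, 64, 32, 16]

    def test_summary_param_total_consistent(self):
        model = AttentionUNet(NetworkCfg(width_multiplier=0.25))
        assert sum(r["params"] for r in model.summary()) == model.param_count()

    def test_gate_override_changes_output(self):
        model = AttentionUNet(NetworkCfg(in_channels=1, width_multiplier=0.125, seed=3))
        x = np.random.default_rng(5).random((1, 1, 64, 64))
        gated = model.predict_proba(x)
        model.set_gate_override(True)
        open_gate = model.predict_proba(x)
        model.set_gate_override(False)
        assert not np.allclose(gated, open_gate)
        np.testing.assert_allclose(model.predict_proba(x), gated)

    def test_forward_deterministic_under_fixed_weights(self):
        model = AttentionUNet(NetworkCfg(in_channels=1, width_multiplier=0.125, seed=2))
        x = np.random.default_rng(9).random((1, 1, 64, 64))
        np.testing.assert_array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_save_load_round_trip(self, tmp_path):
        model = AttentionUNet(NetworkCfg(in_channels=1, width_multiplier=0.125, seed=4))
        x = np.random.default_rng(2).random((1, 1, 64, 64))
        before = model.predict_proba(x)
        model.save(tmp_path / "ckpt.npz")
        loaded = AttentionUNet.load(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(loaded.predict_proba(x), before)
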