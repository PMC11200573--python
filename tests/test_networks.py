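"""Architecture contracts: shapes, attention mechanics, determinism."""

import numpy as np
import pytest

from fquwf.autograd import Tensor
from fquwf.networks import (NetConfig, OpAttention, build_discriminator,
                            build_gde, build_gsr, to_images, to_tensor)


def _rand_images(rng, n, size):
    return rng.uniform(0.0, 1.0, size=(n, size, size, 3))


class TestNetConfig:
    def test_tiny_profile(self):
        cfg = NetConfig.tiny()
        assert cfg.base_channels == 8 and cfg.depth == 2
        assert cfg.scale == 4 and cfg.tiny_mode

    @pytest.mark.parametrize("kw", [{"scale": 3}, {"depth": 0},
                                    {"base_channels": 2}])
    def test_invalid_configs(self, kw):
        with pytest.raises(ValueError):
            NetConfig(**{**{"base_channels": 8, "depth": 2}, **kw})


class TestGDE:
    def test_preserves_spatial_dims(self, tiny_cfg, rng):
        gde = build_gde(tiny_cfg, seed=0)
        out = gde(to_tensor(_rand_images(rng, 2, 64)))
        assert out.shape == (2, 3, 64, 64)

    def test_odd_sizes_padded_and_cropped(self, tiny_cfg, rng):
        gde = build_gde(tiny_cfg, seed=0)
        out = gde(to_tensor(_rand_images(rng, 1, 30)))
        assert out.shape == (1, 3, 30, 30)

    def test_first_conv_box_halves_and_widens(self, tiny_cfg, rng):
        gde = build_gde(tiny_cfg, seed=0)
        feat = gde.enc_convs[0](to_tensor(_rand_images(rng, 1, 64)))
        assert feat.shape == (1, tiny_cfg.base_channels, 32, 32)
        deeper = gde.enc_convs[1](feat)
        assert deeper.shape == (1, 2 * tiny_cfg.base_channels, 16, 16)

    def test_parameter_groups_cover_everything(self, tiny_cfg):
        gde = build_gde(tiny_cfg, seed=0)
        groups = gde.parameter_groups()
        assert set(groups) == {"encoder", "decoder", "attention"}
        grouped = sum(len(g) for g in groups.values())
        assert grouped == len(dict(gde.named_parameters()))

    def test_freezing_encoder_leaves_rest_trainable(self, tiny_cfg, rng):
        gde = build_gde(tiny_cfg, seed=0)
        groups = gde.parameter_groups()
        for p in groups["encoder"].values():
            p.requires_grad = False
        loss = (gde(to_tensor(_rand_images(rng, 2, 16))) ** 2.0).mean()
        gde.zero_grad()
        loss.backward()
        assert all(p.grad is None or not p.grad.any()
                   for p in groups["encoder"].values())
        for name in ("decoder", "attention"):
            assert any(p.grad is not None and p.grad.any()
                       for p in groups[name].values())


class TestOpAttention:
    def test_zeroed_gate_gives_uniform_mixture(self, rng):
        att = OpAttention(4, 3, np.random.default_rng(3))
        att.gate2.weight.data[:] = 0.0
        att.gate2.bias.data[:] = 0.0
        x = Tensor(rng.normal(size=(2, 4, 6, 6)))
        expect = sum(op(x).data for op in att.ops) / 3.0
        np.testing.assert_allclose(att(x).data, expect, atol=1e-12)

    def test_weights_sum_to_one(self, rng):
        att = OpAttention(4, 3, np.random.default_rng(3))
        x = Tensor(rng.normal(size=(5, 4, 6, 6)))
        logits = att.gate2(att.gate1(x.mean(axis=(2, 3))).leaky_relu(0.2))
        w = logits.softmax(axis=1)
        np.testing.assert_allclose(w.data.sum(axis=1), 1.0, atol=1e-12)

    def test_one_hot_identity_conv_passes_input(self, rng):
        att = OpAttention(4, 3, np.random.default_rng(3))
        # make the first candidate (1x1 conv) the identity
        w = att.ops[0].weight
        w.data[:] = 0.0
        for c in range(4):
            w.data[c, c, 0, 0] = 1.0
        att.ops[0].bias.data[:] = 0.0
        # force a (numerically) one-hot gate on that op
        att.gate2.weight.data[:] = 0.0
        att.gate2.bias.data[:] = 0.0
        att.gate2.bias.data[0] = 50.0
        x = Tensor(rng.normal(size=(2, 4, 6, 6)))
        np.testing.assert_allclose(att(x).data, x.data, atol=1e-8)


class TestGSR:
    def test_four_times_upscaling(self, tiny_cfg, rng):
        gsr = build_gsr(tiny_cfg, seed=1)
        out = gsr(to_tensor(_rand_images(rng, 2, 32)))
        assert out.shape == (2, 3, 128, 128)

    def test_zeroed_calibration_conv_gives_zero_image(self, tiny_cfg, rng):
        gsr = build_gsr(tiny_cfg, seed=1)
        gsr.calibrate.weight.data[:] = 0.0
        gsr.calibrate.bias.data[:] = 0.0
        out = gsr(to_tensor(_rand_images(rng, 1, 16)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_untrained_upscaler_close_to_interpolation(self, tiny_cfg, rng):
        gsr = build_gsr(tiny_cfg, seed=1)
        gsr.eval()
        img = _rand_images(rng, 1, 16)
        out = to_images(gsr(to_tensor(img)))[0]
        up = to_images(gsr._upsample(to_tensor(img)))[0]
        assert np.abs(out - up).mean() < 0.1


class TestCritic:
    def test_scalar_scores_in_unit_interval(self, tiny_cfg, rng):
        critic = build_discriminator(tiny_cfg, seed=2)
        scores = critic(to_tensor(_rand_images(rng, 4, 64)))
        assert scores.shape == (4,)
        assert np.all((scores.data > 0.0) & (scores.data < 1.0))

    def test_seeded_builds_differ(self, tiny_cfg, rng):
        a = build_discriminator(tiny_cfg, seed=2)
        b = build_discriminator(tiny_cfg, seed=3)
        x = to_tensor(_rand_images(rng, 2, 32))
        assert (a(x).data != b(x).data).any()

    def test_twin_critics_share_no_storage(self, tiny_cfg, rng):
        dde = build_discriminator(tiny_cfg, seed=2)
        dsr = build_discriminator(tiny_cfg, seed=2)
        for (_, pa), (_, pb) in zip(dde.named_parameters(),
                                    dsr.named_parameters()):
            assert pa.data is not pb.data
        x = to_tensor(_rand_images(rng, 2, 32))
        before = dsr(x).data.copy()
        for p in dde.parameters():
            p.data += 1.0
        np.testing.assert_array_equal(dsr(x).data, before)

    def test_input_below_receptive_field_rejected(self, tiny_cfg, rng):
        critic = build_discriminator(tiny_cfg, seed=2)
        with pytest.raises(ValueError, match="receptive"):
            critic(to_tensor(_rand_images(rng, 1, 4)))


class TestDeterminismAndGradientFlow:
    @pytest.mark.parametrize("builder", [build_gde, build_gsr,
                                         build_discriminator])
    def test_seed_determinism(self, tiny_cfg, builder):
        a = builder(tiny_cfg, seed=9)
        b = builder(tiny_cfg, seed=9)
        for (na, pa), (nb, pb) in zip(a.named_parameters(),
                                      b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)

    @pytest.mark.parametrize("builder,size", [(build_gde, 16),
                                              (build_gsr, 8)])
    def test_no_dead_parameters_in_generators(self, tiny_cfg, rng, builder,
                                              size):
        net = builder(tiny_cfg, seed=4)
        x = to_tensor(rng.normal(0.5, 0.3, size=(4, size, size, 3)))
        loss = (net(x) ** 2.0).mean()
        net.zero_grad()
        loss.backward()
        dead = [n for n, p in net.named_parameters()
                if p.grad is None or not p.grad.any()]
        assert dead == []

    def test_no_dead_parameters_in_critic(self, tiny_cfg, rng):
        critic = build_discriminator(tiny_cfg, seed=4)
        x = to_tensor(rng.normal(0.5, 0.3, size=(4, 32, 32, 3)))
        score = critic(x).clamp(1e-7, 1 - 1e-7)
        loss = -(score.log().mean())
        critic.zero_grad()
        loss.backward()
        dead = [n for n, p in critic.named_parameters()
                if p.grad is None or not p.grad.any()]
        assert dead == []
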