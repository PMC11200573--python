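"""Training mechanics: schedules, patching, freezing, staging, resumption."""

import numpy as np
import pytest

from fquwf import (LossWeights, NetConfig, PhantomParams, StageConfig,
                   StagingError, build_unpaired_dataset, enhance,
                   extract_patches, lr_at, make_pretrain_pairs, pretrain_gde,
                   train_stage_de, train_stage_sr, finetune_macular)
from fquwf.networks import build_gde, build_gsr, build_discriminator, to_tensor
from fquwf.training import augment_patch, snapshot_params


@pytest.fixture(scope="module")
def small_data(tmp_path_factory):
    """A small unpaired dataset for the short stage runs in this module."""
    root = tmp_path_factory.mktemp("traindata")
    params = PhantomParams(size=64, n_drusen=3)
    manifest = build_unpaired_dataset(params, 6, root / "clean", root / "uwf",
                                      seed=21)
    return root, params, manifest


@pytest.fixture(scope="module")
def pretrained(small_data):
    _, params, _ = small_data
    pairs = make_pretrain_pairs(params, 6, seed=33)
    cfg = StageConfig.tiny("PRETRAIN", iterations=60, seed=3)
    gde, anchor = pretrain_gde(pairs, cfg, NetConfig.tiny())
    return gde, anchor, pairs


class TestSchedule:
    @pytest.mark.parametrize("it,expect", [
        (0, 1e-3), (199_999, 1e-3), (200_000, 5e-4), (450_000, 2.5e-4),
    ])
    def test_halving_schedule(self, it, expect):
        assert lr_at(it, 1e-3, 200_000) == pytest.approx(expect, rel=1e-12)

    def test_negative_iteration_rejected(self):
        with pytest.raises(ValueError):
            lr_at(-1, 1e-3, 200_000)


class TestStageConfig:
    def test_default_frozen_groups_per_stage(self):
        assert StageConfig.tiny("PRETRAIN").frozen_groups == frozenset()
        assert StageConfig.tiny("DE").frozen_groups == {"encoder"}
        assert StageConfig.tiny("SR").frozen_groups == {"encoder", "decoder",
                                                        "attention"}
        assert StageConfig.tiny("FT").frozen_groups == frozenset()

    def test_reference_hyperparameters(self):
        cfg = StageConfig("DE")
        assert cfg.batch_size == 16 and cfg.patch_size == 128
        assert cfg.betas == (0.9, 0.999) and cfg.eps == 1e-8
        assert cfg.weight_decay == 1e-2
        assert cfg.lr_halving_period == 200_000

    def test_patch_size_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            StageConfig("DE", patch_size=30)

    def test_unknown_stage(self):
        with pytest.raises(ValueError, match="stage"):
            StageConfig("WARP")


class TestPatches:
    def test_crops_stay_inside_bounds(self, rng):
        img = rng.uniform(size=(256, 256, 3))
        patches = extract_patches(img, 128, n=20, rng=rng)
        assert patches.shape == (20, 128, 128, 3)

    def test_too_small_image_rejected(self, rng):
        with pytest.raises(ValueError, match="smaller"):
            extract_patches(rng.uniform(size=(64, 64, 3)), 128)

    def test_region_constraint_over_many_draws(self, rng):
        img = rng.uniform(size=(128, 128, 3))
        centers = []
        extract_patches(img, 32, n=1000, region=((64, 64), 20), rng=rng,
                        centers_out=centers)
        for r, c in centers:
            assert np.hypot(r - 64, c - 64) <= 20.0 + 1.0   # integer rounding

    def test_rot180_twice_is_identity(self, rng):
        patch = rng.uniform(size=(16, 16, 3))
        twice = augment_patch(augment_patch(patch, 2, False, False),
                              2, False, False)
        np.testing.assert_array_equal(twice, patch)

    def test_flips_are_involutions(self, rng):
        patch = rng.uniform(size=(16, 16, 3))
        f = augment_patch(augment_patch(patch, 0, True, True), 0, True, True)
        np.testing.assert_array_equal(f, patch)

    def test_seeded_determinism(self, rng):
        img = np.random.default_rng(1).uniform(size=(96, 96, 3))
        a = extract_patches(img, 32, n=5, seed=4, augment=True)
        b = extract_patches(img, 32, n=5, seed=4, augment=True)
        np.testing.assert_array_equal(a, b)


class TestPretrain:
    def test_zero_iterations_is_a_noop(self, small_data):
        _, params, _ = small_data
        pairs = make_pretrain_pairs(params, 4, seed=5)
        cfg = StageConfig.tiny("PRETRAIN", iterations=0, seed=3)
        gde, anchor = pretrain_gde(pairs, cfg, NetConfig.tiny())
        fresh = build_gde(NetConfig.tiny(), seed=cfg.seed)
        for (_, a), (_, b) in zip(gde.named_parameters(),
                                  fresh.named_parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_reconstruction_improves_over_untrained(self, pretrained,
                                                    small_data):
        gde, _, _ = pretrained
        _, params, _ = small_data
        holdout = make_pretrain_pairs(params, 4, seed=99)
        untrained = build_gde(NetConfig.tiny(), seed=3)

        def mae(net):
            net.eval()
            return np.mean([
                np.abs(net(to_tensor(d)).data.transpose(0, 2, 3, 1)[0] - c).mean()
                for d, c in holdout])
        assert mae(gde) < mae(untrained)

    def test_anchor_snapshot_matches_parameters(self, pretrained):
        gde, anchor, _ = pretrained
        for name, p in gde.named_parameters():
            np.testing.assert_array_equal(anchor[name], p.data)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            pretrain_gde([], StageConfig.tiny("PRETRAIN"), NetConfig.tiny())


class TestStageDE:
    def test_encoder_frozen_and_losses_logged(self, small_data, pretrained):
        root, _, _ = small_data
        gde, anchor, _ = pretrained
        gde = _clone_gde(gde)
        enc_before = {k: v.data.copy()
                      for k, v in gde.parameter_groups()["encoder"].items()}
        cfg = StageConfig.tiny("DE", iterations=25, seed=5, critic_warmup=5)
        state = train_stage_de(root / "uwf", root / "clean", gde, anchor, cfg,
                               NetConfig.tiny(), LossWeights())
        for k, v in gde.parameter_groups()["encoder"].items():
            np.testing.assert_array_equal(v.data, enc_before[k])
        assert len(state.loss_history) == 25
        for bd in state.loss_history:
            expect = bd.adv_g + 0.5 * bd.identity + 0.1 * bd.anchor
            assert bd.total == pytest.approx(expect, abs=1e-9)

    def test_decoder_and_attention_move(self, small_data, pretrained):
        root, _, _ = small_data
        gde, anchor, _ = pretrained
        gde = _clone_gde(gde)
        groups_before = {
            g: {k: v.data.copy() for k, v in params.items()}
            for g, params in gde.parameter_groups().items()}
        cfg = StageConfig.tiny("DE", iterations=25, seed=5, critic_warmup=5,
                               lr=1e-3, critic_interval=1)
        train_stage_de(root / "uwf", root / "clean", gde, anchor, cfg,
                       NetConfig.tiny(), LossWeights())
        for gname in ("decoder", "attention"):
            moved = any((gde.parameter_groups()[gname][k].data
                         != groups_before[gname][k]).any()
                        for k in groups_before[gname])
            assert moved, f"{gname} parameters did not update"


class TestStageSR:
    def test_enhancer_fully_frozen(self, small_data, pretrained):
        root, _, _ = small_data
        gde, anchor, _ = pretrained
        gde = _clone_gde(gde)
        before = snapshot_params(gde)
        bn_before = {k: v.copy() for k, v in gde.named_buffers()}
        cfg = StageConfig.tiny("SR", iterations=15, seed=6, critic_warmup=5)
        state = train_stage_sr(root / "uwf", root / "clean", gde, None, cfg,
                               NetConfig.tiny(), LossWeights())
        for name, p in gde.named_parameters():
            np.testing.assert_array_equal(p.data, before[name])
        for name, b in gde.named_buffers():
            np.testing.assert_array_equal(b, bn_before[name])
        gsr = state.models["gsr"]
        out = gsr(to_tensor(np.zeros((1, 32, 32, 3))))
        assert out.shape == (1, 3, 128, 128)

    def test_missing_de_checkpoint_is_staging_error(self, small_data, tmp_path):
        root, _, _ = small_data
        cfg = StageConfig.tiny("SR", iterations=1, seed=6)
        with pytest.raises(StagingError):
            train_stage_sr(root / "uwf", root / "clean", None, None, cfg,
                           NetConfig.tiny(), LossWeights(), run_dir=tmp_path)


class TestFinetune:
    def test_macular_crops_joint_updates_and_additivity(self, small_data,
                                                        pretrained):
        root, _, manifest = small_data
        gde, anchor, _ = pretrained
        gde = _clone_gde(gde)
        ncfg = NetConfig.tiny()
        gsr = build_gsr(ncfg, seed=7)
        dde = build_discriminator(ncfg, seed=8)
        dsr = build_discriminator(ncfg, seed=9)
        before_gde = snapshot_params(gde)
        before_gsr = snapshot_params(gsr)
        centers = manifest["macula_centers"]
        pairing = manifest["pairing"]
        uwf_centers = [tuple(np.asarray(centers[pairing[j]]) / 4.0)
                       for j in range(len(pairing))]
        # patch 32 on 64-px phantoms leaves the macular region reachable
        cfg = StageConfig.tiny("FT", iterations=10, seed=7, lr=1e-3,
                               critic_interval=1, patch_size=32)
        state = finetune_macular(root / "uwf", root / "clean", gde, gsr, dde,
                                 dsr, anchor, cfg, ncfg, LossWeights(),
                                 macula_centers=[tuple(c) for c in centers],
                                 uwf_macula_centers=uwf_centers)
        # crop audit: every patch center lies inside its macular region
        for entry in state.crop_log:
            for crop in entry["uwf"] + entry["fundus"]:
                (cy, cx), radius = crop["region"]
                r, c = crop["center"]
                assert np.hypot(r - cy, c - cx) <= radius + 1.0
        # nothing frozen: both generators moved
        assert any((p.data != before_gde[n]).any()
                   for n, p in gde.named_parameters())
        assert any((p.data != before_gsr[n]).any()
                   for n, p in gsr.named_parameters())
        # logged total equals the sum of the stage losses
        for bd in state.loss_history:
            expect = (bd.adv_g + 0.5 * bd.identity + 0.1 * bd.anchor
                      + 0.5 * bd.cycle)
            assert bd.total == pytest.approx(expect, abs=1e-6)

    def test_missing_stages_is_staging_error(self, small_data):
        root, _, _ = small_data
        cfg = StageConfig.tiny("FT", iterations=1, seed=7)
        with pytest.raises(StagingError):
            finetune_macular(root / "uwf", root / "clean", None, None, None,
                             None, None, cfg, NetConfig.tiny(), LossWeights())


class TestResumability:
    def test_save_load_step_equals_straight_run(self, small_data, pretrained,
                                                tmp_path):
        root, _, _ = small_data
        base_gde, anchor, _ = pretrained
        ncfg = NetConfig.tiny()
        w = LossWeights()

        def fresh():
            g = _clone_gde(base_gde)
            return g

        straight_cfg = StageConfig.tiny("DE", iterations=6, seed=12,
                                        critic_warmup=3)
        ga = fresh()
        train_stage_de(root / "uwf", root / "clean", ga, anchor,
                       straight_cfg, ncfg, w)

        part_cfg = StageConfig.tiny("DE", iterations=4, seed=12,
                                    critic_warmup=3)
        gb = fresh()
        train_stage_de(root / "uwf", root / "clean", gb, anchor, part_cfg,
                       ncfg, w, run_dir=tmp_path)
        gc = fresh()
        resume_cfg = StageConfig.tiny("DE", iterations=6, seed=12,
                                      critic_warmup=3)
        train_stage_de(root / "uwf", root / "clean", gc, anchor, resume_cfg,
                       ncfg, w, run_dir=tmp_path, resume=True)

        for (na, pa), (_, pc) in zip(ga.named_parameters(),
                                     gc.named_parameters()):
            np.testing.assert_array_equal(pa.data, pc.data), na


class TestEnhance:
    def test_shape_composition_and_intermediate(self, tiny_cfg):
        gde = build_gde(tiny_cfg, seed=0)
        gsr = build_gsr(tiny_cfg, seed=1)
        img = np.random.default_rng(0).uniform(size=(64, 64, 3))
        out, inter = enhance(img, gde, gsr, return_intermediate=True)
        assert out.shape == (256, 256, 3)
        assert inter.shape == (64, 64, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_sr_first_ablation_is_distinct(self, tiny_cfg):
        gde = build_gde(tiny_cfg, seed=0)
        gsr = build_gsr(tiny_cfg, seed=1)
        img = np.random.default_rng(0).uniform(size=(32, 32, 3))
        a = enhance(img, gde, gsr, order="de_sr")
        b = enhance(img, gde, gsr, order="sr_de")
        assert a.shape == b.shape == (128, 128, 3)
        assert (a != b).any()

    def test_unknown_order_rejected(self, tiny_cfg):
        gde = build_gde(tiny_cfg, seed=0)
        gsr = build_gsr(tiny_cfg, seed=1)
        with pytest.raises(ValueError, match="order"):
            enhance(np.zeros((32, 32, 3)), gde, gsr, order="both")


def _clone_gde(gde):
    from fquwf.networks import build_gde as _build
    clone = _build(NetConfig.tiny(), seed=0)
    clone.load_state_dict({k: v.copy() for k, v in gde.state_dict().items()})
    return clone
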