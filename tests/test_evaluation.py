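"""Metric oracles: sharpness, IoU/mAP, ANOVA, Bonferroni, blob detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from fquwf.degradations import gaussian_blur
from fquwf.evaluation import (anova_oneway, bonferroni_pairwise,
                              detect_bright_blobs, fid_adapter, iou,
                              lpips_adapter, map_score, sharpness_score,
                              upscale_mask, build_report)


class TestSharpness:
    def test_monotone_in_blur_strength(self, vessel_phantom):
        scores = [sharpness_score(gaussian_blur(vessel_phantom, s))
                  for s in (3, 5, 7)]
        assert scores[0] < scores[1] < scores[2]
        assert sharpness_score(vessel_phantom) < scores[0]

    def test_constant_image_convention(self):
        assert sharpness_score(np.full((32, 32, 3), 0.5)) == 1.0

    def test_checkerboard_is_sharp(self):
        board = np.indices((32, 32)).sum(axis=0) % 2
        img = np.repeat(board[..., None], 3, axis=2).astype(float)
        assert sharpness_score(img) < 0.5

    def test_range_and_tiny_image_rejected(self, vessel_phantom):
        assert 0.0 <= sharpness_score(vessel_phantom) <= 1.0
        with pytest.raises(ValueError, match="small"):
            sharpness_score(np.zeros((8, 8, 3)))


class TestIoU:
    def test_identical_nonempty(self):
        m = np.zeros((4, 4), bool)
        m[1:3, 1:3] = True
        assert iou(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4), bool); a[0, 0] = True
        b = np.zeros((4, 4), bool); b[3, 3] = True
        assert iou(a, b) == 0.0

    def test_half_overlap_oracle(self):
        a = np.ones((2, 2), bool)
        b = np.zeros((2, 2), bool); b[:, 0] = True
        assert iou(a, b) == 0.5

    def test_both_empty_convention(self):
        assert iou(np.zeros((3, 3), bool), np.zeros((3, 3), bool)) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            iou(np.zeros((3, 3), bool), np.zeros((4, 4), bool))

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_matches_pixel_count_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((16, 16)) > 0.6
        b = rng.random((16, 16)) > 0.6
        inter = union = 0
        for i in range(16):
            for j in range(16):
                inter += a[i, j] and b[i, j]
                union += a[i, j] or b[i, j]
        expect = 1.0 if union == 0 else inter / union
        assert iou(a, b) == pytest.approx(expect, abs=1e-12)
        assert iou(b, a) == iou(a, b)


class TestMapScore:
    def test_perfect_masks(self):
        m = np.ones((4, 4), bool)
        assert map_score([(m, m), (m, m)]) == 100.0

    def test_mean_of_extremes(self):
        full = np.ones((4, 4), bool)
        empty = np.zeros((4, 4), bool)
        assert map_score([(full, full), (empty, full)]) == 50.0

    def test_order_invariance(self):
        full = np.ones((4, 4), bool)
        empty = np.zeros((4, 4), bool)
        pairs = [(full, full), (empty, full), (full, empty)]
        assert map_score(pairs) == map_score(pairs[::-1])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="pair"):
            map_score([])


class TestAnova:
    def test_identical_groups(self):
        assert anova_oneway([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]) == (0.0, 1.0)

    def test_zero_within_variance_sentinel(self):
        F, p = anova_oneway([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
        assert F == float("inf") and p == 0.0

    def test_hand_computed_example(self):
        F, p = anova_oneway([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])
        assert F == pytest.approx(1.5, abs=1e-12)

    def test_matches_scipy_on_random_groups(self, rng):
        for _ in range(20):
            groups = [rng.normal(size=rng.integers(3, 9)) for _ in range(3)]
            F, p = anova_oneway(groups)
            ref = sps.f_oneway(*groups)
            assert F == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="two samples"):
            anova_oneway([[1.0], [2.0, 3.0]])


class TestBonferroni:
    def test_two_groups_single_comparison(self, rng):
        out = bonferroni_pairwise([rng.normal(size=5), rng.normal(size=5)])
        assert len(out) == 1
        assert out[0]["p_adjusted"] == pytest.approx(out[0]["p_raw"])

    def test_four_groups_emit_six_comparisons(self, rng):
        out = bonferroni_pairwise([rng.normal(size=4) for _ in range(4)])
        assert len(out) == 6

    def test_capping_at_one(self, rng):
        # similar groups -> raw p near 1, adjusted must cap at 1.0
        g = [rng.normal(size=50) for _ in range(4)]
        out = bonferroni_pairwise(g)
        for r in out:
            assert r["p_adjusted"] == pytest.approx(min(1.0, 6 * r["p_raw"]))
            assert 0.0 <= r["p_adjusted"] <= 1.0

    def test_matches_scipy_welch(self, rng):
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=9)
        out = bonferroni_pairwise([a, b])
        ref = sps.ttest_ind(a, b, equal_var=False).pvalue
        assert out[0]["p_raw"] == pytest.approx(ref, abs=1e-12)


class TestAdapters:
    def test_lpips_absent_marker_or_zero_on_identical(self, rng):
        img = rng.uniform(size=(32, 32, 3))
        value = lpips_adapter(img, img)
        try:
            import lpips  # noqa: F401
            import torch  # noqa: F401
        except ImportError:
            # graceful-degradation contract: no backend, no fake number
            assert value is None
        else:
            assert value <= 1e-6

    def test_fid_absent_marker_without_backend(self, tmp_path):
        value = fid_adapter(tmp_path, tmp_path)
        try:
            import cleanfid  # noqa: F401
        except ImportError:
            try:
                import pytorch_fid  # noqa: F401
            except ImportError:
                assert value is None


class TestBlobDetection:
    def _scene(self, rng, centers, radius=2.0, bright=0.3):
        img = np.full((96, 96, 3), 0.4)
        img += rng.normal(0, 0.005, size=img.shape)
        mask = np.zeros((96, 96), bool)
        rr, cc = np.mgrid[0:96, 0:96]
        for y, x in centers:
            disk = np.hypot(rr - y, cc - x) <= radius
            img[disk] += bright
            mask |= disk
        return np.clip(img, 0, 1), mask

    def test_recovers_planted_blobs(self, rng):
        img, mask = self._scene(rng, [(46, 50), (50, 44), (42, 46)])
        det = detect_bright_blobs(img, center=(47, 47), radius=16)
        assert iou(det, mask) > 0.5

    def test_silent_on_flat_image(self, rng):
        img = np.full((96, 96, 3), 0.4) + rng.normal(0, 0.002, (96, 96, 3))
        det = detect_bright_blobs(img, center=(47, 47), radius=16)
        assert det.sum() <= 4

    def test_ignores_blobs_outside_macular_disk(self, rng):
        img, _ = self._scene(rng, [(10, 10)])
        det = detect_bright_blobs(img, center=(47, 47), radius=16)
        assert not det[:20, :20].any()

    def test_upscale_mask_block_replication(self):
        m = np.array([[True, False], [False, True]])
        up = upscale_mask(m, 2)
        assert up.shape == (4, 4)
        assert up[:2, :2].all() and up[2:, 2:].all()
        assert not up[:2, 2:].any()


class TestReport:
    def test_structure_and_ranges(self, tmp_path, rng):
        from fquwf import PhantomParams, build_unpaired_dataset
        build_unpaired_dataset(PhantomParams(size=64), 3,
                               tmp_path / "clean", tmp_path / "uwf", seed=3)
        report = build_report(tmp_path / "uwf", tmp_path / "clean")
        assert len(report["per_image"]) == 3
        for row in report["per_image"]:
            assert 0.0 <= row["gamma"] <= 1.0
        agg = report["aggregate"]
        assert 0.0 <= agg["gamma_mean"] <= 1.0
        assert 0.0 <= report["stats"]["anova_p"] <= 1.0
        for pw in report["stats"]["pairwise"]:
            assert 0.0 <= pw["p_adjusted"] <= 1.0
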