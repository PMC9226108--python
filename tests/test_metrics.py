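import math

import numpy as np
import pytest

import sonotkv as sk
from _oracles import (oracle_auc, oracle_confusion, oracle_hd95, oracle_overlap)


def mask3(arr):
    return sk.SegmentationMask(voxels=np.asarray(arr, dtype=np.uint8),
                               spacing=(1, 1, 1))


class TestConfusionCounts:
    def test_identical_masks_have_no_errors(self):
        rng = np.random.default_rng(0)
        a = (rng.random((6, 6, 6)) < 0.4).astype(np.uint8)
        tp, fp, fn, tn = sk.confusion_counts(a, a)
        assert fp == 0 and fn == 0
        assert tp == a.sum() and tp + tn == a.size

    def test_complement_masks_have_no_agreement(self):
        rng = np.random.default_rng(1)
        a = (rng.random((6, 6, 6)) < 0.4).astype(np.uint8)
        tp, fp, fn, tn = sk.confusion_counts(1 - a, a)
        assert tp == 0 and tn == 0

    def test_two_by_two_toy_enumeration(self):
        pred = np.array([[1, 1], [0, 0]])
        ref = np.array([[1, 0], [1, 0]])
        assert sk.confusion_counts(pred, ref) == (1, 1, 1, 1)

    def test_counts_partition_the_volume(self):
        rng = np.random.default_rng(2)
        a = (rng.random((5, 7, 3)) < 0.3).astype(np.uint8)
        b = (rng.random((5, 7, 3)) < 0.5).astype(np.uint8)
        tp, fp, fn, tn = sk.confusion_counts(a, b)
        assert tp + fp + fn + tn == a.size

    def test_shape_mismatch_and_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            sk.confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="binary"):
            sk.confusion_counts(np.full((2, 2), 2), np.zeros((2, 2)))


class TestOverlapMetrics:
    def test_balanced_counts_give_zero_mcc(self):
        dsc, jac, fnr, mcc, vs, _ = sk.overlap_metrics(2, 2, 2, 2)
        assert mcc == pytest.approx(0.0)

    def test_dsc_080_maps_to_jaccard_067(self):
        # the printed DSC/Jaccard pair is consistent with J = D/(2-D)
        tp, fp_fn = 8, 4  # dsc = 16/20 = 0.80
        dsc, jac, *_ = sk.overlap_metrics(tp, fp_fn // 2, fp_fn // 2, 10)
        assert dsc == pytest.approx(0.80)
        assert jac == pytest.approx(0.80 / (2 - 0.80))
        assert jac == pytest.approx(2 / 3, abs=5e-4)

    def test_perfect_prediction(self):
        dsc, jac, fnr, mcc, vs, flags = sk.overlap_metrics(10, 0, 0, 20)
        assert (dsc, jac, vs) == (1.0, 1.0, 1.0)
        assert fnr == 0.0 and mcc == pytest.approx(1.0)
        assert flags == []

    def test_empty_masks_flagged_not_silent(self):
        dsc, jac, fnr, mcc, vs, flags = sk.overlap_metrics(0, 0, 0, 9)
        assert "empty_masks" in flags and "fn_rate_undefined" in flags
        assert dsc == 1.0 and math.isnan(fnr)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            sk.overlap_metrics(0, 0, 0, 0)


class TestHD95:
    def test_identical_masks_give_zero(self):
        rng = np.random.default_rng(3)
        a = np.zeros((8, 8, 8), np.uint8)
        a[2:6, 2:6, 2:6] = 1
        assert sk.hd95(a, a) == 0.0

    def test_two_single_voxels_five_apart(self):
        a = np.zeros((12, 3, 3), np.uint8); a[2, 1, 1] = 1
        b = np.zeros((12, 3, 3), np.uint8); b[7, 1, 1] = 1
        assert sk.hd95(a, b) == pytest.approx(5.0)

    def test_spacing_scales_distances(self):
        a = np.zeros((12, 3, 3), np.uint8); a[2, 1, 1] = 1
        b = np.zeros((12, 3, 3), np.uint8); b[7, 1, 1] = 1
        assert sk.hd95(a, b, spacing=(2.0, 1.0, 1.0)) == pytest.approx(10.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        a = (rng.random((8, 8, 8)) < 0.3).astype(np.uint8)
        b = (rng.random((8, 8, 8)) < 0.3).astype(np.uint8)
        assert sk.hd95(a, b) == pytest.approx(sk.hd95(b, a))

    def test_empty_mask_rejected(self):
        a = np.zeros((4, 4, 4), np.uint8)
        b = np.zeros((4, 4, 4), np.uint8); b[1, 1, 1] = 1
        with pytest.raises(ValueError, match="empty"):
            sk.hd95(a, b)

    def test_directed_mean_variant_available(self):
        rng = np.random.default_rng(5)
        a = (rng.random((8, 8, 8)) < 0.3).astype(np.uint8)
        b = (rng.random((8, 8, 8)) < 0.3).astype(np.uint8)
        pooled = sk.hd95(a, b, variant="pooled")
        directed = sk.hd95(a, b, variant="directed_mean")
        assert pooled >= 0 and directed >= 0


class TestROCAUC:
    def test_perfect_probabilities(self):
        ref = np.array([0, 1, 0, 1, 1], np.uint8)
        assert sk.roc_auc(ref.astype(float), ref) == 1.0

    def test_constant_probability_is_chance(self):
        ref = np.array([0, 1, 0, 1], np.uint8)
        assert sk.roc_auc(np.full(4, 0.7), ref) == pytest.approx(0.5)

    def test_six_voxel_toy_eight_ninths(self):
        prob = np.array([0.9, 0.8, 0.4, 0.7, 0.3, 0.1])
        ref = np.array([1, 1, 1, 0, 0, 0], np.uint8)
        assert sk.roc_auc(prob, ref) == pytest.approx(8 / 9)

    def test_single_class_reference_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            sk.roc_auc(np.array([0.1, 0.9]), np.array([1, 1], np.uint8))

    def test_matches_sklearn_on_random_volumes(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(6)
        for _ in range(10):
            prob = rng.random(200)
            ref = (rng.random(200) < 0.3).astype(np.uint8)
            if ref.sum() in (0, 200):
                continue
            assert sk.roc_auc(prob, ref) == pytest.approx(
                roc_auc_score(ref, prob), abs=1e-12)


class TestOracleEquivalence:
    def test_panel_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            a = (rng.random((8, 8, 8)) < 0.35).astype(np.uint8)
            b = (rng.random((8, 8, 8)) < 0.35).astype(np.uint8)
            counts = sk.confusion_counts(a, b)
            assert counts == oracle_confusion(a, b)
            got = sk.overlap_metrics(*counts)[:5]
            want = oracle_overlap(*counts)
            for g, w in zip(got, want):
                if math.isnan(w):
                    assert math.isnan(g)
                else:
                    assert g == pytest.approx(w, abs=1e-9)
            if a.any() and b.any():
                assert sk.hd95(a, b) == pytest.approx(oracle_hd95(a, b), abs=1e-9)
            prob = rng.random((8, 8, 8))
            if 0 < b.sum() < b.size:
                assert sk.roc_auc(prob, b) == pytest.approx(
                    oracle_auc(prob, b), abs=1e-9)


class TestMetricReportInvariants:
    def test_jaccard_identity_and_vs_dominates_dsc(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = (rng.random((6, 6, 6)) < rng.uniform(0.1, 0.6)).astype(np.uint8)
            b = (rng.random((6, 6, 6)) < rng.uniform(0.1, 0.6)).astype(np.uint8)
            if not (a.any() and b.any()):
                continue
            dsc, jac, _, _, vs, _ = sk.overlap_metrics(*sk.confusion_counts(a, b))
            assert jac == pytest.approx(dsc / (2 - dsc), abs=1e-12)
            assert vs >= dsc - 1e-12

    def test_mcc_invariant_under_simultaneous_label_swap(self):
        rng = np.random.default_rng(8)
        a = (rng.random((6, 6, 6)) < 0.4).astype(np.uint8)
        b = (rng.random((6, 6, 6)) < 0.4).astype(np.uint8)
        m1 = sk.overlap_metrics(*sk.confusion_counts(a, b))[3]
        m2 = sk.overlap_metrics(*sk.confusion_counts(1 - a, 1 - b))[3]
        assert m1 == pytest.approx(m2, abs=1e-12)

    def test_evaluate_pair_restricts_to_kept_frames(self):
        a = np.zeros((4, 4, 6), np.uint8); a[1:3, 1:3, 2:4] = 1
        pm, rm = mask3(a), mask3(a)
        full = sk.evaluate_pair(pm, rm)
        sub = sk.evaluate_pair(pm, rm, frames=[2, 3])
        assert sub.tn < full.tn           # background outside kept frames dropped
        assert sub.dsc == full.dsc == 1.0


class TestSliceDecileProfile:
    def build(self, z_extent=20, size=8):
        vox = np.zeros((size, size, z_extent + 4), np.uint8)
        vox[2:6, 2:6, 2:2 + z_extent] = 1
        return mask3(vox)

    def test_identical_masks_flat_at_one(self):
        ref = self.build()
        prof = sk.slice_decile_dsc(ref, ref)
        assert prof.slice_extent == (2, 21)
        assert all(v == pytest.approx(1.0) for v in prof.dsc_by_decile)

    def test_first_decile_deleted_gives_zero_then_ones(self):
        ref = self.build()
        pred_vox = ref.voxels.copy()
        z0, z1 = 2, 21
        length = z1 - z0 + 1
        first_bin = [z for z in range(z0, z1 + 1)
                     if int(10 * (z - z0) / length) == 0]
        pred_vox[:, :, first_bin] = 0
        prof = sk.slice_decile_dsc(mask3(pred_vox), ref)
        assert prof.dsc_by_decile[0] == 0.0
        assert all(v == pytest.approx(1.0) for v in prof.dsc_by_decile[1:])

    def test_twenty_frame_extent_bins_exactly_two_frames(self):
        ref = self.build(z_extent=20)
        z0, z1 = 2, 21
        length = z1 - z0 + 1
        bins = [[] for _ in range(10)]
        for z in range(z0, z1 + 1):
            bins[min(int(10 * (z - z0) / length), 9)].append(z)
        assert all(len(b) == 2 for b in bins)

    def test_empty_reference_rejected(self):
        empty = mask3(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="empty"):
            sk.slice_decile_dsc(empty, empty)

    def test_uniformly_degraded_masks_keep_centre_over_ends(self):
        """Uniform erosion hurts thin end slices more than thick centre
        slices, reproducing the clinical profile shape."""
        from scipy.ndimage import binary_erosion

        spec = sk.sample_spec(3, "centered")
        _, gt, _ = sk.render_phantom(spec)
        eroded = binary_erosion(gt.voxels, iterations=2).astype(np.uint8)
        prof = sk.slice_decile_dsc(
            sk.SegmentationMask(voxels=eroded, spacing=gt.spacing), gt)
        vals = prof.dsc_by_decile
        centre = np.nanmean(vals[3:7])
        ends = np.nanmean([vals[0], vals[9]])
        assert centre >= ends

    def test_frame_mean_mode(self):
        ref = self.build()
        prof = sk.slice_decile_dsc(ref, ref, mode="frame_mean")
        assert all(v == pytest.approx(1.0) for v in prof.dsc_by_decile)


def test_summarize_reports_mean_and_sd():
    a = np.zeros((4, 4, 4), np.uint8); a[1:3, 1:3, 1:3] = 1
    r1 = sk.evaluate_pair(mask3(a), mask3(a))
    b = a.copy(); b[0, 0, 0] = 1
    r2 = sk.evaluate_pair(mask3(b), mask3(a))
    summ = sk.summarize_reports([r1, r2])
    assert summ["dsc"]["n"] == 2
    assert summ["dsc"]["mean"] == pytest.approx((r1.dsc + r2.dsc) / 2)
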