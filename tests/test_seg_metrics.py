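import numpy as np
import pytest

from segrefine import (
    BinaryMask,
    ConfusionCounts,
    UsageError,
    border_strip,
    combine_masks,
    confusion_counts,
    dice,
    evaluate_pair,
    hd95,
    jaccard,
    over_seg,
    summarize,
    under_seg,
)
from segrefine.phantom import perturb_mask
from segrefine.seg_metrics import boundary_voxels

from conftest import random_mask_pair


def brute_force_counts(gt, pred):
    tp = fp = fn = tn = 0
    for g, p in zip(gt.ravel(), pred.ravel()):
        if g and p:
            tp += 1
        elif not g and p:
            fp += 1
        elif g and not p:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def brute_force_hd95(gt, pred, spacing):
    """All-pairs boundary-distance oracle, independent of the KD-tree path."""
    a = boundary_voxels(gt) * np.asarray(spacing, float)
    b = boundary_voxels(pred) * np.asarray(spacing, float)
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))
    return max(np.percentile(d.min(axis=1), 95), np.percentile(d.min(axis=0), 95))


class TestConfusionCounts:
    def test_identical_masks(self):
        m = np.zeros((4, 4, 4), dtype=np.uint8)
        m.ravel()[:10] = 1
        c = confusion_counts(BinaryMask(m), BinaryMask(m))
        assert (c.tp, c.fp, c.fn, c.tn) == (10, 0, 0, 54)

    def test_empty_prediction(self):
        gt = np.zeros((4, 4, 4), dtype=np.uint8)
        gt[1:3, 1:3, 1:3] = 1
        c = confusion_counts(BinaryMask(gt), BinaryMask(np.zeros_like(gt)))
        assert (c.tp, c.fp, c.fn) == (0, 0, 8)
        assert c.tn == 64 - 8

    def test_matches_brute_force_on_random_pair(self):
        rng = np.random.default_rng(0)
        a, b = random_mask_pair(rng, (8, 8, 8))
        c = confusion_counts(BinaryMask(a), BinaryMask(b))
        assert (c.tp, c.fp, c.fn, c.tn) == brute_force_counts(a, b)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(UsageError):
            confusion_counts(
                BinaryMask(np.zeros((4, 4, 4), np.uint8)),
                BinaryMask(np.zeros((4, 4, 5), np.uint8)),
            )


class TestOverlapMetrics:
    def test_hand_example(self):
        c = ConfusionCounts(tp=6, fp=2, fn=2, tn=54)
        assert dice(c) == pytest.approx(0.75)
        assert jaccard(c) == pytest.approx(0.6)
        assert over_seg(c) == pytest.approx(0.25)
        assert under_seg(c) == pytest.approx(0.25)
        assert over_seg(c) + under_seg(c) == pytest.approx(2 * (1 - dice(c)))

    def test_perfect_match(self):
        c = ConfusionCounts(tp=9, fp=0, fn=0, tn=55)
        assert (dice(c), jaccard(c), over_seg(c), under_seg(c)) == (1.0, 1.0, 0.0, 0.0)

    def test_empty_prediction_under_seg_reaches_two(self):
        c = ConfusionCounts(tp=0, fp=0, fn=12, tn=52)
        assert dice(c) == 0.0
        assert over_seg(c) == 0.0
        assert under_seg(c) == pytest.approx(2.0)

    def test_both_empty_convention(self):
        c = ConfusionCounts(tp=0, fp=0, fn=0, tn=64)
        assert dice(c) == 1.0 and jaccard(c) == 1.0
        assert over_seg(c) == 0.0 and under_seg(c) == 0.0


class TestHD95:
    def test_identical_masks_zero(self):
        m = np.zeros((6, 6, 6), dtype=np.uint8)
        m[2:4, 2:4, 2:4] = 1
        assert hd95(BinaryMask(m), BinaryMask(m)) == 0.0

    def test_single_voxels_closed_form(self):
        a = np.zeros((8, 8, 8), dtype=np.uint8)
        b = np.zeros_like(a)
        a[2, 2, 2] = 1
        b[2, 2, 5] = 1  # 3 voxels apart along axis 2
        assert hd95(BinaryMask(a), BinaryMask(b), spacing=(1, 1, 2)) == pytest.approx(6.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a, b = random_mask_pair(rng, (16, 16, 16))
            a[0, 0, 0] = b[0, 0, 1] = 1  # guarantee non-empty
            spacing = (0.8, 1.0, 2.0)
            got = hd95(BinaryMask(a), BinaryMask(b), spacing)
            assert got == pytest.approx(brute_force_hd95(a, b, spacing), abs=1e-9)

    def test_symmetric_and_below_exact_hausdorff(self):
        rng = np.random.default_rng(2)
        a, b = random_mask_pair(rng, (12, 12, 12))
        a[5, 5, 5] = b[6, 6, 6] = 1
        ma, mb = BinaryMask(a), BinaryMask(b)
        assert hd95(ma, mb) == hd95(mb, ma)
        pa = boundary_voxels(a).astype(float)
        pb = boundary_voxels(b).astype(float)
        d = np.sqrt(((pa[:, None] - pb[None]) ** 2).sum(axis=2))
        hd100 = max(d.min(axis=1).max(), d.min(axis=0).max())
        assert hd95(ma, mb) <= hd100 + 1e-12

    def test_scales_linearly_with_spacing(self):
        rng = np.random.default_rng(3)
        a, b = random_mask_pair(rng, (10, 10, 10))
        a[4, 4, 4] = b[5, 5, 5] = 1
        ma, mb = BinaryMask(a), BinaryMask(b)
        one = hd95(ma, mb, (1, 1, 1))
        three = hd95(ma, mb, (3, 3, 3))
        assert three == pytest.approx(3 * one)

    def test_empty_mask_rejected(self):
        m = np.zeros((4, 4, 4), dtype=np.uint8)
        m[1, 1, 1] = 1
        with pytest.raises(UsageError):
            hd95(BinaryMask(m), BinaryMask(np.zeros_like(m)))


class TestBorderStrip:
    def test_solid_cube_loses_one_voxel_shell(self):
        m = np.zeros((13, 13, 13), dtype=np.uint8)
        m[2:11, 2:11, 2:11] = 1  # solid 9^3
        out = border_strip(BinaryMask(m), 3)
        expected = np.zeros_like(m)
        expected[3:10, 3:10, 3:10] = 1  # solid 7^3
        np.testing.assert_array_equal(out.data, expected)

    def test_thin_mask_vanishes(self):
        m = np.zeros((8, 8, 8), dtype=np.uint8)
        m[3, :, :] = 1
        assert border_strip(BinaryMask(m), 5).data.sum() == 0

    def test_edge_one_is_identity(self):
        rng = np.random.default_rng(4)
        m = BinaryMask((rng.random((8, 8, 8)) < 0.5).astype(np.uint8))
        np.testing.assert_array_equal(border_strip(m, 1).data, m.data)

    def test_even_edge_rejected(self):
        with pytest.raises(UsageError):
            border_strip(BinaryMask(np.ones((4, 4, 4), np.uint8)), 4)

    def test_anti_monotone_in_cube_edge(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = BinaryMask((rng.random((10, 10, 10)) < 0.6).astype(np.uint8))
            s3 = border_strip(m, 3).data
            s5 = border_strip(m, 5).data
            assert np.all(s5 <= s3) and np.all(s3 <= m.data)


class TestCombineMasks:
    def test_same_mask_fixed_point(self):
        rng = np.random.default_rng(6)
        m = BinaryMask((rng.random((6, 6, 6)) < 0.5).astype(np.uint8))
        for op in ("union", "intersection"):
            np.testing.assert_array_equal(combine_masks(m, m, op).data, m.data)

    def test_disjoint_masks(self):
        a = np.zeros((6, 6, 6), dtype=np.uint8)
        b = np.zeros_like(a)
        a[:2], b[4:] = 1, 1
        union = combine_masks(BinaryMask(a), BinaryMask(b), "union")
        inter = combine_masks(BinaryMask(a), BinaryMask(b), "intersection")
        assert union.data.sum() == a.sum() + b.sum()
        assert inter.data.sum() == 0

    def test_truth_table_on_random_pair(self):
        rng = np.random.default_rng(7)
        a, b = random_mask_pair(rng, (8, 8, 8))
        union = combine_masks(BinaryMask(a), BinaryMask(b), "union").data
        inter = combine_masks(BinaryMask(a), BinaryMask(b), "intersection").data
        np.testing.assert_array_equal(union, (a.astype(bool) | b.astype(bool)).astype(np.uint8))
        np.testing.assert_array_equal(inter, a * b)  # Hadamard product


class TestEvaluatePair:
    def test_identical_phantom_masks(self, phantom0):
        _, _, gt = phantom0
        r = evaluate_pair(gt, gt, gt.spacing)
        assert (r.dice, r.jaccard, r.os, r.us, r.hd95) == (1.0, 1.0, 0.0, 0.0, 0.0)

    def test_erosion_creates_only_under_segmentation(self, phantom0):
        _, _, gt = phantom0
        r = evaluate_pair(gt, perturb_mask(gt, "erode_boundary", 2, seed=0), gt.spacing)
        assert r.os == 0.0 and r.us > 0.0

    def test_dilation_creates_only_over_segmentation(self, phantom0):
        _, _, gt = phantom0
        r = evaluate_pair(gt, perturb_mask(gt, "dilate_leak", 3, seed=0), gt.spacing)
        assert r.us == 0.0 and r.os > 0.0

    def test_metric_identities_on_random_pairs(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            a, b = random_mask_pair(rng, (8, 8, 8))
            r = evaluate_pair(BinaryMask(a), BinaryMask(b))
            assert r.os + r.us == pytest.approx(2 * (1 - r.dice), abs=1e-9)
            assert r.jaccard == pytest.approx(r.dice / (2 - r.dice), abs=1e-9)


class TestSummarize:
    def test_single_report_sd_zero_with_warning(self, caplog):
        r = evaluate_pair(
            BinaryMask(np.ones((4, 4, 4), np.uint8)), BinaryMask(np.ones((4, 4, 4), np.uint8))
        )
        with caplog.at_level("WARNING"):
            table = summarize([r])
        assert table.loc["dice", "mean"] == 1.0
        assert table.loc["dice", "sd"] == 0.0
        assert any("single report" in rec.message for rec in caplog.records)

    def test_two_reports_mean_and_median(self):
        from segrefine import MetricReport

        reports = [
            MetricReport(dice=0.9, jaccard=0.8, os=0.1, us=0.1, hd95=2.0),
            MetricReport(dice=0.7, jaccard=0.6, os=0.3, us=0.3, hd95=4.0),
        ]
        table = summarize(reports)
        assert table.loc["dice", "mean"] == pytest.approx(0.8)
        assert table.loc["dice", "median"] == pytest.approx(0.8)
        assert table.loc["dice", "sd"] == pytest.approx(np.std([0.9, 0.7], ddof=1))

    def test_permutation_invariant(self):
        from segrefine import MetricReport

        reports = [
            MetricReport(dice=d, jaccard=d / (2 - d), os=0.0, us=2 * (1 - d), hd95=h)
            for d, h in [(0.9, 1.0), (0.8, 2.0), (0.95, 0.5)]
        ]
        t1 = summarize(reports)
        t2 = summarize(list(reversed(reports)))
        # summation order may differ; statistics must agree to float precision
        np.testing.assert_allclose(t1.to_numpy(), t2.to_numpy(), rtol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(UsageError):
            summarize([])
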