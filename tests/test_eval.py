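"""Detection metrics: exact count identities, hand-computed AP examples, and
agreement with the independent loop-based protocol oracle."""

import numpy as np
import pytest

from paddydetr.evaluation import (
    annotations_to_gts,
    average_precision,
    evaluate,
    map50,
    match_detections,
    operating_point,
    pr_curve_auc,
    size_stratified,
)
from paddydetr.synthetic import SyntheticSceneConfig, generate_scene

from coco_oracle import class_ap, mean_ap50, size_metrics


def noisy_predictions(gts, rng, jitter=4.0, p_miss=0.15, p_fp=0.4, p_wrong=0.1, span=200):
    """Detector-like output: jittered copies of ground truths plus clutter."""
    preds = []
    for truths in gts:
        dets = []
        for cls, (x1, y1, x2, y2) in truths:
            if rng.random() < p_miss:
                continue
            d = rng.normal(0, jitter, size=4)
            box = (x1 + d[0], y1 + d[1], max(x2 + d[2], x1 + d[0] + 1), max(y2 + d[3], y1 + d[1] + 1))
            c = int(rng.integers(0, 3)) if rng.random() < p_wrong else cls
            dets.append((c, float(np.clip(rng.normal(0.8, 0.15), 0.05, 1.0)), box))
        n_fp = rng.poisson(p_fp * max(len(truths), 1))
        for _ in range(n_fp):
            x1, y1 = rng.uniform(0, span - 20, size=2)
            w, h = rng.uniform(5, 60, size=2)
            dets.append(
                (int(rng.integers(0, 3)), float(rng.uniform(0.05, 0.9)), (x1, y1, x1 + w, y1 + h))
            )
        preds.append(dets)
    return preds


def scene_collection(n, seed=0, canvas=200):
    from dataclasses import replace

    cfg = SyntheticSceneConfig(
        canvas_size=canvas, n_single=3, n_patch=1, n_ridge=1,
        single_side=(10, 40), patch_side=(60, 90), ridge_thickness=(14, 24),
        background_texture=12,
    )
    master = np.random.default_rng(seed)
    return [generate_scene(replace(cfg, seed=int(master.integers(2**31)))) for _ in range(n)]


class TestCounts:
    def test_precision_recall_identities(self):
        """precision = TP/(TP+FP) and recall = TP/(TP+FN) on integer counts."""
        gts = [[(0, (0, 0, 10, 10)), (0, (20, 20, 30, 30))]]
        preds = [[(0, 0.9, (0, 0, 10, 10)), (0, 0.8, (50, 50, 60, 60))]]
        tp, fp, fn = match_detections(preds, gts, 0.5)
        assert (tp, fp, fn) == (1, 1, 1)
        p, r = operating_point(preds, gts)
        assert p == tp / (tp + fp) == 0.5
        assert r == tp / (tp + fn) == 0.5

    def test_eight_tp_two_fp_gives_point_eight_precision(self):
        gts = [[(0, (i * 20, 0, i * 20 + 10, 10)) for i in range(8)]]
        preds = [[(0, 0.9, (i * 20, 0, i * 20 + 10, 10)) for i in range(8)]
                 + [(0, 0.8, (500 + i * 50, 0, 510 + i * 50, 10)) for i in range(2)]]
        p, _ = operating_point(preds, gts)
        assert p == pytest.approx(0.8)

    def test_eight_tp_eight_fn_gives_half_recall(self):
        gts = [[(0, (i * 20, 0, i * 20 + 10, 10)) for i in range(16)]]
        preds = [[(0, 0.9, (i * 20, 0, i * 20 + 10, 10)) for i in range(8)]]
        _, r = operating_point(preds, gts)
        assert r == pytest.approx(0.5)

    def test_greedy_matching_matches_loop_oracle_on_crafted_scene(self, rng):
        """A 10-box scene with overlapping candidates, against the independent
        loop implementation of the same greedy rule."""
        gts = [[(0, (10, 10, 30, 30)), (0, (25, 25, 45, 45)), (1, (60, 60, 80, 80))]]
        preds = [[
            (0, 0.95, (11, 11, 31, 31)),
            (0, 0.90, (12, 12, 32, 32)),   # duplicate of the first gt
            (0, 0.85, (26, 26, 44, 44)),
            (1, 0.80, (61, 61, 79, 79)),
            (1, 0.70, (0, 0, 5, 5)),
            (0, 0.60, (70, 10, 90, 30)),
            (2, 0.55, (60, 60, 80, 80)),   # right box, wrong class
        ]]
        tp, fp, fn = match_detections(preds, gts, 0.5)
        from coco_oracle import match_one_class

        o_tp = o_fp = 0
        npos_total = 0
        for cls in range(3):
            records, npos = match_one_class(preds, gts, cls, 0.5)
            o_tp += sum(1 for _, k in records if k == "tp")
            o_fp += sum(1 for _, k in records if k == "fp")
            npos_total += npos
        assert (tp, fp) == (o_tp, o_fp)
        assert fn == npos_total - o_tp

    def test_no_predictions_precision_nan_recall_zero(self):
        gts = [[(0, (0, 0, 10, 10))]]
        p, r = operating_point([[(0, 0.3, (0, 0, 10, 10))]], gts, score_thr=0.5)
        assert np.isnan(p)
        assert r == 0.0


class TestAveragePrecision:
    def test_perfect_detection_unit_ap(self):
        gts = [[(0, (0, 0, 10, 10))], [(0, (5, 5, 25, 25))]]
        preds = [[(0, 1.0, (0, 0, 10, 10))], [(0, 1.0, (5, 5, 25, 25))]]
        assert average_precision(preds, gts, 0, 0.5) == pytest.approx(1.0)

    def test_zero_detections_zero_ap(self):
        gts = [[(0, (0, 0, 10, 10))]]
        assert average_precision([[]], gts, 0, 0.5) == 0.0

    def test_absent_class_excluded_from_mean(self):
        gts = [[(0, (0, 0, 10, 10))]]
        preds = [[(0, 1.0, (0, 0, 10, 10))]]
        assert average_precision(preds, gts, 2, 0.5) is None
        assert map50(preds, gts) == pytest.approx(1.0)

    def test_worked_six_detection_example(self):
        """6 detections over 4 ground truths, AP from a hand-built envelope.

        Score order: TP FP TP FP TP FP -> precision at recalls (.25,.5,.75)
        after envelope: 1, 2/3, 3/5; recall never reaches 1.
        AP = (26*1 + 25*(2/3) + 25*(3/5)) / 101.
        """
        gts = [[(0, (i * 50, 0, i * 50 + 20, 20)) for i in range(4)]]
        preds = [[
            (0, 0.95, (0, 0, 20, 20)),
            (0, 0.90, (300, 300, 320, 320)),
            (0, 0.85, (50, 0, 70, 20)),
            (0, 0.80, (400, 400, 420, 420)),
            (0, 0.75, (100, 0, 120, 20)),
            (0, 0.70, (500, 500, 520, 520)),
        ]]
        expected = (26 * 1.0 + 25 * (2 / 3) + 25 * (3 / 5)) / 101
        assert average_precision(preds, gts, 0, 0.5) == pytest.approx(expected, abs=1e-9)

    def test_duplicate_scores_deterministic_tie_break(self):
        gts = [[(0, (0, 0, 10, 10))]]
        preds = [[(0, 0.5, (100, 100, 110, 110)), (0, 0.5, (0, 0, 10, 10))]]
        ap1 = average_precision(preds, gts, 0, 0.5)
        ap2 = average_precision([list(preds[0])], gts, 0, 0.5)
        assert ap1 == ap2  # index order breaks the tie, stably


class TestSizeStratified:
    def test_only_small_objects_leaves_other_strata_undefined(self):
        gts = [[(0, (0, 0, 10, 10))]]
        preds = [[(0, 1.0, (0, 0, 10, 10))]]
        ap, ar = size_stratified(preds, gts)
        assert ap["small"] == pytest.approx(1.0)
        assert ap["medium"] == -1.0 and ap["large"] == -1.0
        assert ar["medium"] == -1.0 and ar["large"] == -1.0

    def test_perfect_small_set_unit_ap_and_ar(self):
        gts = [[(0, (0, 0, 20, 20)), (1, (40, 40, 60, 60))]]
        preds = [[(0, 1.0, (0, 0, 20, 20)), (1, 0.9, (40, 40, 60, 60))]]
        ap, ar = size_stratified(preds, gts)
        assert ap["small"] == pytest.approx(1.0)
        assert ar["small"] == pytest.approx(1.0)

    def test_strata_partition_ground_truths(self, rng):
        scenes = scene_collection(5, seed=2)
        gts = annotations_to_gts(scenes)
        from paddydetr.data import classify_size

        for truths in gts:
            for _, box in truths:
                area = (box[2] - box[0]) * (box[3] - box[1])
                assert classify_size(area) is not None  # exactly one stratum fires


class TestPRCurve:
    def test_perfect_detector_unit_auc(self):
        gts = [[(0, (0, 0, 10, 10))]]
        preds = [[(0, 0.9, (0, 0, 10, 10))]]
        _, auc = pr_curve_auc(preds, gts)
        assert auc == pytest.approx(1.0)

    def test_pure_false_positives_zero_auc(self):
        gts = [[(0, (0, 0, 10, 10))]]
        preds = [[(0, 0.9, (100, 100, 120, 120))]]
        _, auc = pr_curve_auc(preds, gts)
        assert auc == 0.0

    def test_crafted_curve_trapezoid_area(self):
        """5 gts detected at descending scores with one interleaved FP:
        hand-integrated trapezoid over the recall sweep."""
        gts = [[(0, (i * 50, 0, i * 50 + 20, 20)) for i in range(5)]]
        preds = [[
            (0, 0.9, (0, 0, 20, 20)),
            (0, 0.8, (50, 0, 70, 20)),
            (0, 0.7, (999, 999, 1020, 1020)),
            (0, 0.6, (100, 0, 120, 20)),
            (0, 0.5, (150, 0, 170, 20)),
        ]]
        points, auc = pr_curve_auc(preds, gts)
        # thresholds: .9 -> (0.2, 1), .8 -> (0.4, 1), .7 -> (0.4, 2/3),
        # .6 -> (0.6, 3/4), .5 -> (0.8, 4/5)
        expected_points = [(0.2, 1.0), (0.4, 1.0), (0.4, 2 / 3), (0.6, 0.75), (0.8, 0.8)]
        assert sorted(points) == pytest.approx(sorted(expected_points))
        rs = [0.0, 0.2, 0.4, 0.4, 0.6, 0.8]
        ps = [1.0, 1.0, 2 / 3, 1.0, 0.75, 0.8]
        order = np.argsort(rs, kind="stable")
        expected_auc = np.trapezoid(np.array(ps)[order], np.array(rs)[order])
        assert auc == pytest.approx(expected_auc, abs=1e-9)


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_full_suite_matches_loop_oracle(self, seed):
        scenes = scene_collection(10, seed=seed)
        gts = annotations_to_gts(scenes)
        preds = noisy_predictions(gts, np.random.default_rng(seed + 100))
        assert map50(preds, gts) == pytest.approx(mean_ap50(preds, gts), abs=1e-4)
        for cls in range(3):
            mine = average_precision(preds, gts, cls, 0.5)
            ref = class_ap(preds, gts, cls, 0.5)
            if ref is None:
                assert mine is None
            else:
                assert mine == pytest.approx(ref, abs=1e-4)
        ap_mine, ar_mine = size_stratified(preds, gts)
        ap_ref, ar_ref = size_metrics(preds, gts)
        for k in ("small", "medium", "large"):
            assert ap_mine[k] == pytest.approx(ap_ref[k], abs=1e-4)
            assert ar_mine[k] == pytest.approx(ar_ref[k], abs=1e-4)


class TestSummary:
    def test_evaluate_bundles_consistent_fields(self):
        scenes = scene_collection(4, seed=5)
        gts = annotations_to_gts(scenes)
        preds = noisy_predictions(gts, np.random.default_rng(42))
        s = evaluate(preds, gts)
        assert s.tp + s.fn == sum(len(g) for g in gts)
        if s.tp + s.fp > 0:
            assert s.precision == pytest.approx(s.tp / (s.tp + s.fp))
        assert 0 <= s.map50 <= 1
        assert 0 <= s.auc_pr <= 1
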