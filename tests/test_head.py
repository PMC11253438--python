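"""Set-prediction head: decoding contract, Hungarian matching optimality,
loss closed forms and the rasterized GIoU oracle."""

import itertools
import math

import numpy as np
import pytest

from paddydetr.head import (
    DETRDecoder,
    DetectionSet,
    MatchWeights,
    NO_OBJECT,
    box_losses,
    classification_loss,
    classification_loss_from_logits,
    cxcywh_to_xyxy,
    giou_matrix,
    hungarian_match,
    iou_matrix,
    match_cost_matrix,
    xyxy_to_cxcywh,
)
from paddydetr.nn import Tensor


def random_detection_set(rng, q=6):
    logits = rng.normal(size=(q, 4))
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs = e / e.sum(axis=1, keepdims=True)
    boxes = np.clip(rng.random((q, 4)), 0.05, 0.95)
    boxes[:, 2:] *= 0.5
    return DetectionSet(class_probs=probs, boxes=boxes)


def brute_force_min_cost(cost):
    """Exhaustive minimum over injective gt -> query assignments."""
    n_gt, n_q = cost.shape
    best = None
    for perm in itertools.permutations(range(n_q), n_gt):
        c = sum(cost[g, q] for g, q in enumerate(perm))
        if best is None or c < best:
            best = c
    return best


class TestBoxGeometry:
    def test_cxcywh_roundtrip(self, rng):
        b = rng.random((10, 4))
        np.testing.assert_allclose(xyxy_to_cxcywh(cxcywh_to_xyxy(b)), b, atol=1e-12)

    def test_iou_identical_and_disjoint(self):
        a = np.array([[0, 0, 2, 2]])
        assert iou_matrix(a, a)[0, 0] == 1.0
        assert iou_matrix(a, np.array([[5, 5, 6, 6]]))[0, 0] == 0.0

    def test_giou_against_rasterized_oracle(self):
        """GIoU of two unit-normalized boxes vs a 1000x1000 pixel-grid count."""
        a_c = np.array([0.25, 0.25, 0.5, 0.5])
        b_c = np.array([0.5, 0.5, 0.5, 0.5])
        a, b = cxcywh_to_xyxy(a_c), cxcywh_to_xyxy(b_c)
        n = 1000
        yy, xx = np.mgrid[0:n, 0:n]
        cx, cy = (xx + 0.5) / n, (yy + 0.5) / n

        def inside(box):
            return (cx >= box[0]) & (cx < box[2]) & (cy >= box[1]) & (cy < box[3])

        ia, ib = inside(a), inside(b)
        inter = (ia & ib).sum() / n**2
        union = (ia | ib).sum() / n**2
        iou_pix = inter / union
        hull = (max(a[2], b[2]) - min(a[0], b[0])) * (max(a[3], b[3]) - min(a[1], b[1]))
        giou_pix = iou_pix - (hull - union) / hull
        assert iou_pix == pytest.approx(1 / 7, abs=1e-3)
        got = giou_matrix(a[None], b[None])[0, 0]
        assert got == pytest.approx(giou_pix, abs=1e-3)

    def test_giou_far_disjoint_approaches_minus_one(self):
        a = np.array([[0, 0, 1, 1]])
        b = np.array([[999, 999, 1000, 1000]])
        assert giou_matrix(a, b)[0, 0] == pytest.approx(-1.0, abs=1e-2)


class TestHungarian:
    def test_single_pair_matched(self, rng):
        preds = random_detection_set(rng, q=3)
        gts = [(1, np.array([0.5, 0.5, 0.2, 0.2]))]
        res = hungarian_match(preds, gts)
        assert set(res.assignment) == {0}

    def test_no_ground_truths_empty_match(self, rng):
        res = hungarian_match(random_detection_set(rng), [])
        assert res.assignment == {} and res.cost == 0.0

    def test_more_gts_than_queries_rejected(self, rng):
        preds = random_detection_set(rng, q=2)
        gts = [(0, np.array([0.5, 0.5, 0.2, 0.2]))] * 3
        with pytest.raises(ValueError):
            hungarian_match(preds, gts)

    @pytest.mark.parametrize("seed", range(10))
    def test_optimal_vs_exhaustive_permutations(self, seed):
        r = np.random.default_rng(seed)
        n_gt = int(r.integers(1, 5))
        q = int(r.integers(n_gt, 7))
        preds = random_detection_set(r, q=q)
        gts = [
            (int(r.integers(0, 3)), np.clip(r.random(4), 0.1, 0.9)) for _ in range(n_gt)
        ]
        res = hungarian_match(preds, gts)
        cost = match_cost_matrix(
            preds.class_probs,
            preds.boxes,
            np.array([g[0] for g in gts]),
            np.stack([g[1] for g in gts]),
            MatchWeights(),
        ).T
        assert res.cost == pytest.approx(brute_force_min_cost(cost), abs=1e-9)

    def test_assignment_is_injective(self, rng):
        preds = random_detection_set(rng, q=5)
        gts = [(0, np.clip(rng.random(4), 0.1, 0.9)) for _ in range(4)]
        res = hungarian_match(preds, gts)
        assert len(set(res.assignment.values())) == len(res.assignment) == 4


class TestLosses:
    def test_perfect_prediction_zero_ce(self):
        probs = np.eye(4)[[0, 1, 2]]
        assert classification_loss(probs, [0, 1, 2]) == pytest.approx(0.0, abs=1e-7)

    def test_single_item_e_inverse(self):
        probs = np.array([[math.exp(-1), 1 - math.exp(-1), 0, 0]])
        assert classification_loss(probs, [0]) == pytest.approx(1.0, rel=1e-6)

    def test_uniform_four_classes_ln4(self):
        probs = np.full((1, 4), 0.25)
        assert classification_loss(probs, [2]) == pytest.approx(math.log(4), rel=1e-6)

    def test_zero_probability_clamped_not_error(self):
        probs = np.array([[0.0, 1.0, 0.0, 0.0]])
        loss = classification_loss(probs, [0])
        assert np.isfinite(loss) and loss == pytest.approx(-math.log(1e-8))

    def test_no_object_down_weighting(self):
        probs = np.full((2, 4), 0.25)
        # one matched item + one no-object item at weight 0.1
        loss = classification_loss(probs, [1, NO_OBJECT], no_object_weight=0.1)
        assert loss == pytest.approx((1.0 + 0.1) * math.log(4) / 1.1, rel=1e-6)

    def test_logits_form_matches_probability_form(self, rng):
        logits = rng.normal(size=(5, 4)).astype(np.float32)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs = e / e.sum(axis=1, keepdims=True)
        labels = np.array([0, 1, 2, NO_OBJECT, 1])
        a = classification_loss_from_logits(Tensor(logits), labels)
        b = classification_loss(probs, labels)
        assert float(a.data) == pytest.approx(b, rel=1e-5)

    def test_identical_boxes_zero_loss(self):
        b = np.array([[0.5, 0.5, 0.2, 0.2]])
        l1, giou = box_losses(b, b)
        assert l1 == 0.0 and giou == pytest.approx(0.0, abs=1e-9)

    def test_far_disjoint_giou_loss_near_two(self):
        a = np.array([[0.01, 0.01, 0.01, 0.01]])
        b = np.array([[0.99, 0.99, 0.01, 0.01]])
        _, giou = box_losses(a, b)
        assert giou == pytest.approx(2.0, abs=0.05)

    def test_tensor_path_matches_numpy_path(self, rng):
        pred = np.clip(rng.random((4, 4)), 0.1, 0.9).astype(np.float32)
        gt = np.clip(rng.random((4, 4)), 0.1, 0.9)
        l1_t, giou_t = box_losses(Tensor(pred), gt)
        l1_n, giou_n = box_losses(pred, gt)
        assert float(l1_t.data) == pytest.approx(l1_n, rel=1e-5)
        assert float(giou_t.data) == pytest.approx(giou_n, rel=1e-4)


class TestDecoder:
    def test_detection_set_contract(self, rng):
        dec = DETRDecoder(32, rng, num_queries=7, layers=2, heads=4, ffn_ratio=2)
        dec.eval()
        from paddydetr.head import decode

        y3 = Tensor(rng.random((2, 32, 4, 4)).astype(np.float32))
        sets = decode(y3, dec)
        assert len(sets) == 2
        for ds in sets:
            assert ds.class_probs.shape == (7, 4)
            np.testing.assert_allclose(ds.class_probs.sum(axis=1), 1.0, atol=1e-6)
            assert ((ds.boxes >= 0) & (ds.boxes <= 1)).all()

    def test_single_query_degenerate_config(self, rng):
        dec = DETRDecoder(16, rng, num_queries=1, layers=1, heads=2, ffn_ratio=2)
        dec.eval()
        from paddydetr.head import decode

        (ds,) = decode(Tensor(rng.random((1, 16, 2, 2)).astype(np.float32)), dec)
        assert ds.class_probs.shape == (1, 4)
        np.testing.assert_allclose(ds.class_probs.sum(), 1.0, atol=1e-6)

    def test_eval_runs_identical(self, rng):
        dec = DETRDecoder(16, rng, num_queries=3, layers=1, heads=2, ffn_ratio=2)
        dec.eval()
        y3 = Tensor(rng.random((1, 16, 2, 2)).astype(np.float32))
        a = dec(y3)[-1]
        b = dec(y3)[-1]
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[1].data, b[1].data)

    def test_queries_produce_distinct_outputs(self, rng):
        dec = DETRDecoder(32, rng, num_queries=6, layers=2, heads=4, ffn_ratio=2)
        dec.eval()
        logits, boxes = dec(Tensor(rng.random((1, 32, 4, 4)).astype(np.float32)))[-1]
        assert np.abs(np.diff(logits.data[0], axis=0)).max() > 1e-4


class TestSetSymmetry:
    def test_ground_truth_permutation_leaves_loss_unchanged(self, rng):
        from paddydetr.model import WeedDetector, tiny_config

        model = WeedDetector(tiny_config(0))
        x = Tensor(rng.random((1, 3, 64, 64)).astype(np.float32))
        outs = model(x)
        gts = [
            (0, np.array([0.5, 0.2, 0.9, 0.1])),
            (1, np.array([0.3, 0.6, 0.2, 0.2])),
            (2, np.array([0.7, 0.7, 0.3, 0.3])),
        ]
        _, bd1 = model.compute_loss(outs, [gts])
        _, bd2 = model.compute_loss(outs, [[gts[2], gts[0], gts[1]]])
        assert bd1.total == pytest.approx(bd2.total, rel=1e-6)
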