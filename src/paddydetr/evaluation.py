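"""Detection metrics.

Inputs are per-image lists:

* detections: ``(class_index, score, (x1, y1, x2, y2))``
* ground truths: ``(class_index, (x1, y1, x2, y2))``

The protocol follows COCO throughout: greedy score-ordered matching with
per-class separation, 101-point interpolated average precision, size strata
small/medium/large on box area (boundaries 32^2 and 96^2), AP/AR over the
IoU grid 0.50:0.05:0.95, average recall at up to 100 detections per image.
Undefined values (no predictions / empty stratum) are reported as sentinels
(NaN for the precision of an empty prediction set, -1 for an empty stratum),
never silently as perfect scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SizeClass, classify_size
from .head import NUM_CLASSES, iou_matrix

IOU_GRID = np.round(np.arange(0.50, 0.96, 0.05), 2)
RECALL_GRID = np.linspace(0.0, 1.0, 101)
MAX_DETECTIONS = 100


@dataclass
class EvalSummary:
    tp: int
    fp: int
    fn: int
    precision: float  # NaN when no predictions survive the score threshold
    recall: float
    per_class_ap50: dict
    map50: float
    size_ap: dict  # {'small': .., 'medium': .., 'large': ..}; -1 if stratum empty
    size_ar: dict
    pr_curve: list = field(default_factory=list)  # (recall, precision) points
    auc_pr: float = 0.0


def _box_area(box) -> float:
    return max(box[2] - box[0], 0.0) * max(box[3] - box[1], 0.0)


# ---------------------------------------------------------------------------
# counting at a fixed operating point
# ---------------------------------------------------------------------------
def match_detections(preds: list, gts: list, iou_thr: float = 0.5):
    """Greedy TP/FP/FN counting over an image collection.

    Detections are visited in descending score order (ties broken by list
    position); each is a true positive if it overlaps an unmatched
    ground truth of the same class at IoU >= iou_thr, else a false positive.
    Unmatched ground truths are false negatives.
    """
    tp = fp = fn = 0
    for dets, truths in zip(preds, gts):
        order = sorted(range(len(dets)), key=lambda i: (-dets[i][1], i))
        matched = [False] * len(truths)
        for i in order:
            cls, _, box = dets[i]
            best_iou, best_j = 0.0, -1
            for j, (gcls, gbox) in enumerate(truths):
                if matched[j] or gcls != cls:
                    continue
                iou = float(iou_matrix([box], [gbox])[0, 0])
                if iou >= iou_thr and iou > best_iou:
                    best_iou, best_j = iou, j
            if best_j >= 0:
                matched[best_j] = True
                tp += 1
            else:
                fp += 1
        fn += matched.count(False)
    return tp, fp, fn


def operating_point(preds: list, gts: list, score_thr: float = 0.5, iou_thr: float = 0.5):
    """(precision, recall) with detections filtered at score >= score_thr.

    With no surviving predictions, precision is undefined and reported NaN;
    recall is 0 when ground truths exist.
    """
    filtered = [[d for d in dets if d[1] >= score_thr] for dets in preds]
    tp, fp, fn = match_detections(filtered, gts, iou_thr)
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    if tp + fp == 0 and tp + fn > 0:
        recall = 0.0
    return precision, recall


# ---------------------------------------------------------------------------
# average precision / recall (COCO protocol)
# ---------------------------------------------------------------------------
def _match_class(
    preds: list,
    gts: list,
    class_index: int,
    iou_thr: float,
    size_class: SizeClass | None = None,
    max_dets: int | None = None,
):
    """Score-ordered matching for one class (optionally one size stratum).

    Returns (scores, is_tp, is_ignored, npos).  Ground truths outside the
    stratum are 'ignore': detections may match them without being scored;
    unmatched detections whose own area lies outside the stratum are also
    ignored (COCO convention).
    """
    all_scores, all_tp, all_ignore = [], [], []
    npos = 0
    for dets, truths in zip(preds, gts):
        cls_dets = [(i, d) for i, d in enumerate(dets) if d[0] == class_index]
        cls_dets.sort(key=lambda t: (-t[1][1], t[0]))
        if max_dets is not None:
            cls_dets = cls_dets[:max_dets]
        cls_gts = [(g[1], size_class is not None and classify_size(max(_box_area(g[1]), 1e-9)) != size_class)
                   for g in truths if g[0] == class_index]
        npos += sum(1 for _, ign in cls_gts if not ign)
        matched = [False] * len(cls_gts)
        for _, (cls, score, box) in cls_dets:
            best_iou, best_j, best_ign = 0.0, -1, False
            for j, (gbox, g_ign) in enumerate(cls_gts):
                if matched[j]:
                    continue
                iou = float(iou_matrix([box], [gbox])[0, 0])
                if iou < iou_thr:
                    continue
                # prefer any non-ignored match over an ignored one
                if best_j >= 0 and not best_ign and g_ign:
                    continue
                if iou > best_iou or (best_ign and not g_ign):
                    best_iou, best_j, best_ign = iou, j, g_ign
            if best_j >= 0:
                matched[best_j] = True
                all_scores.append(score)
                all_tp.append(not best_ign)
                all_ignore.append(best_ign)
            else:
                ignore = size_class is not None and classify_size(
                    max(_box_area(box), 1e-9)
                ) != size_class
                all_scores.append(score)
                all_tp.append(False)
                all_ignore.append(ignore)
    return (
        np.asarray(all_scores, dtype=np.float64),
        np.asarray(all_tp, dtype=bool),
        np.asarray(all_ignore, dtype=bool),
        npos,
    )


def _ap_from_matches(scores, is_tp, is_ignore, npos) -> float | None:
    if npos == 0:
        return None
    keep = ~is_ignore
    scores, is_tp = scores[keep], is_tp[keep]
    order = np.argsort(-scores, kind="stable")
    is_tp = is_tp[order]
    tp_cum = np.cumsum(is_tp)
    fp_cum = np.cumsum(~is_tp)
    if len(is_tp) == 0:
        return 0.0
    recall = tp_cum / npos
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    # precision envelope: monotone non-increasing from the right
    for i in range(len(precision) - 2, -1, -1):
        precision[i] = max(precision[i], precision[i + 1])
    # 101-point interpolation; the 1e-10 guards exact-recall grid hits against
    # float rounding (13/20 vs linspace's 0.65)
    idx = np.searchsorted(recall, RECALL_GRID - 1e-10, side="left")
    interp = np.where(idx < len(precision), precision[np.minimum(idx, len(precision) - 1)], 0.0)
    return float(interp.mean())


def average_precision(preds: list, gts: list, class_index: int, iou_thr: float = 0.5):
    """COCO 101-point AP for one class; None when the class has no ground truths."""
    scores, is_tp, is_ign, npos = _match_class(preds, gts, class_index, iou_thr)
    return _ap_from_matches(scores, is_tp, is_ign, npos)


def map50(preds: list, gts: list) -> float:
    """Mean AP at IoU 0.5 over the classes present in the ground truth."""
    aps = [average_precision(preds, gts, c, 0.5) for c in range(NUM_CLASSES)]
    defined = [a for a in aps if a is not None]
    return float(np.mean(defined)) if defined else float("nan")


def size_stratified(preds: list, gts: list):
    """AP and AR per COCO size stratum, averaged over IoU 0.50:0.05:0.95.

    AR uses at most 100 detections per image.  Empty strata report -1.
    """
    ap_out, ar_out = {}, {}
    for sc in SizeClass:
        aps, ars = [], []
        for thr in IOU_GRID:
            cls_aps, cls_ars = [], []
            for c in range(NUM_CLASSES):
                scores, is_tp, is_ign, npos = _match_class(
                    preds, gts, c, thr, size_class=sc, max_dets=MAX_DETECTIONS
                )
                ap = _ap_from_matches(scores, is_tp, is_ign, npos)
                if ap is not None:
                    cls_aps.append(ap)
                    cls_ars.append(is_tp.sum() / npos)
            if cls_aps:
                aps.append(np.mean(cls_aps))
                ars.append(np.mean(cls_ars))
        ap_out[sc.value] = float(np.mean(aps)) if aps else -1.0
        ar_out[sc.value] = float(np.mean(ars)) if ars else -1.0
    return ap_out, ar_out


def pr_curve_auc(preds: list, gts: list, iou_thr: float = 0.5):
    """Pooled precision-recall curve over score thresholds and its area.

    All classes are pooled (class-aware matching); the area is the trapezoid
    integral over recall, anchored at recall 0 with the highest-threshold
    precision.
    """
    scores = sorted({d[1] for dets in preds for d in dets}, reverse=True)
    points = []
    for thr in scores:
        filtered = [[d for d in dets if d[1] >= thr] for dets in preds]
        tp, fp, fn = match_detections(filtered, gts, iou_thr)
        if tp + fp == 0:
            continue
        points.append((tp / max(tp + fn, 1), tp / (tp + fp)))
    points.sort(key=lambda p: p[0])
    if not points:
        return [], 0.0
    rs = [0.0] + [p[0] for p in points]
    ps = [points[0][1]] + [p[1] for p in points]
    auc = float(np.trapezoid(ps, rs))
    return points, auc


def evaluate(preds: list, gts: list, score_thr: float = 0.5) -> EvalSummary:
    """Full metric suite for a prediction/ground-truth collection."""
    filtered = [[d for d in dets if d[1] >= score_thr] for dets in preds]
    tp, fp, fn = match_detections(filtered, gts, 0.5)
    precision, recall = operating_point(preds, gts, score_thr, 0.5)
    per_class = {c: average_precision(preds, gts, c, 0.5) for c in range(NUM_CLASSES)}
    size_ap, size_ar = size_stratified(preds, gts)
    curve, auc = pr_curve_auc(preds, gts)
    return EvalSummary(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        per_class_ap50=per_class,
        map50=map50(preds, gts),
        size_ap=size_ap,
        size_ar=size_ar,
        pr_curve=curve,
        auc_pr=auc,
    )


def annotations_to_gts(images: list) -> list:
    """AnnotatedImage list -> per-image ground-truth tuples (class_index, xyxy)."""
    return [[(a.label_index, a.box) for a in img.annotations] for img in images]
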