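"""Independent loop-based implementation of the COCO detection protocol.

Written directly from the protocol's definition (greedy score-ordered
matching per image, best-IoU tie-break, ignore semantics for out-of-stratum
ground truths, precision envelope, 101-point interpolated AP, AR at 100
detections) with no code shared with the package's evaluator; used to
cross-check it.
"""

from __future__ import annotations


def box_iou(a, b) -> float:
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    ix = min(ax2, bx2) - max(ax1, bx1)
    iy = min(ay2, by2) - max(ay1, by1)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


def box_area(b) -> float:
    return (b[2] - b[0]) * (b[3] - b[1])


def in_stratum(area: float, stratum: str | None) -> bool:
    if stratum is None:
        return True
    if stratum == "small":
        return area <= 32.0**2
    if stratum == "medium":
        return 32.0**2 < area <= 96.0**2
    return area > 96.0**2


def match_one_class(preds, gts, cls, thr, stratum=None, max_dets=None):
    """Returns (records, npos); records are (score, kind) with kind in
    {'tp', 'fp', 'ignored'} in arbitrary order."""
    records = []
    npos = 0
    for dets, truths in zip(preds, gts):
        my_dets = [(i, d) for i, d in enumerate(dets) if d[0] == cls]
        my_dets.sort(key=lambda t: (-t[1][1], t[0]))
        if max_dets is not None:
            my_dets = my_dets[:max_dets]
        my_gts = []
        for g in truths:
            if g[0] == cls:
                ignore = not in_stratum(box_area(g[1]), stratum)
                my_gts.append([g[1], ignore, False])  # box, ignore, matched
                if not ignore:
                    npos += 1
        for _, (c, score, box) in my_dets:
            best = -1
            best_iou = 0.0
            for j, (gbox, g_ign, g_matched) in enumerate(my_gts):
                if g_matched:
                    continue
                iou = box_iou(box, gbox)
                if iou < thr:
                    continue
                if best >= 0 and not my_gts[best][1] and g_ign:
                    continue  # never trade a real match for an ignored one
                if iou > best_iou or (best >= 0 and my_gts[best][1] and not g_ign):
                    best, best_iou = j, iou
            if best >= 0:
                my_gts[best][2] = True
                records.append((score, "ignored" if my_gts[best][1] else "tp"))
            else:
                kind = "ignored" if not in_stratum(box_area(box), stratum) else "fp"
                if stratum is None:
                    kind = "fp"
                records.append((score, kind))
    return records, npos


def ap_101(records, npos):
    """101-point interpolated AP from (score, kind) records."""
    if npos == 0:
        return None
    kept = [(s, k) for s, k in records if k != "ignored"]
    kept.sort(key=lambda t: -t[0])
    precisions, recalls = [], []
    tp = fp = 0
    for _, kind in kept:
        if kind == "tp":
            tp += 1
        else:
            fp += 1
        precisions.append(tp / (tp + fp))
        recalls.append(tp / npos)
    # envelope
    for i in range(len(precisions) - 2, -1, -1):
        precisions[i] = max(precisions[i], precisions[i + 1])
    total = 0.0
    for k in range(101):
        r = k / 100.0
        p = 0.0
        for prec, rec in zip(precisions, recalls):
            if rec >= r - 1e-10:
                p = prec
                break
        total += p
    return total / 101.0


def class_ap(preds, gts, cls, thr):
    return ap_101(*match_one_class(preds, gts, cls, thr))


def mean_ap50(preds, gts, n_classes=3):
    aps = [class_ap(preds, gts, c, 0.5) for c in range(n_classes)]
    defined = [a for a in aps if a is not None]
    return sum(defined) / len(defined) if defined else float("nan")


def size_metrics(preds, gts, n_classes=3):
    """AP/AR per stratum averaged over the IoU grid, -1 for empty strata."""
    thrs = [0.5 + 0.05 * i for i in range(10)]
    ap_out, ar_out = {}, {}
    for stratum in ("small", "medium", "large"):
        ap_acc, ar_acc = [], []
        for thr in thrs:
            cls_ap, cls_ar = [], []
            for c in range(n_classes):
                records, npos = match_one_class(preds, gts, c, thr, stratum, max_dets=100)
                ap = ap_101(records, npos)
                if ap is not None:
                    cls_ap.append(ap)
                    n_tp = sum(1 for _, k in records if k == "tp")
                    cls_ar.append(n_tp / npos)
            if cls_ap:
                ap_acc.append(sum(cls_ap) / len(cls_ap))
                ar_acc.append(sum(cls_ar) / len(cls_ar))
        ap_out[stratum] = sum(ap_acc) / len(ap_acc) if ap_acc else -1.0
        ar_out[stratum] = sum(ar_acc) / len(ar_acc) if ar_acc else -1.0
    return ap_out, ar_out
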