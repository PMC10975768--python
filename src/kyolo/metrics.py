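"""Detection metrics: confusion counts, precision/recall, NMS, and mAP.

Precision is TP/(TP+FP) and recall TP/(TP+FN); with detections there is no
meaningful true-negative count. AP is the area under the interpolated
precision-recall curve (101-point interpolation); mAP@0.5-0.95 averages AP
over IoU thresholds 0.5, 0.55, ..., 0.95. With a single class mAP equals
AP.

Detections are (boxes, scores) pairs per image, boxes in center-size form
(normalized or pixels, as long as detections and ground truth agree).
Matching is greedy: detections in descending score order each claim the
highest-IoU unmatched ground-truth box of their image at or above the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxes import pairwise_iou

__all__ = [
    "ConfusionCounts", "MetricsReport", "precision_recall", "nms",
    "match_detections", "average_precision", "COCO_IOU_THRESHOLDS",
]

COCO_IOU_THRESHOLDS = tuple(np.round(np.arange(0.5, 1.0, 0.05), 2))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricsReport:
    """Evaluation summary for a (single-class) detection run."""

    counts: ConfusionCounts
    precision: float
    recall: float
    ap_per_threshold: dict = field(default_factory=dict)  # iou_thr -> AP
    map50: float = 0.0
    map50_95: float = 0.0
    num_classes: int = 1

    def as_dict(self) -> dict:
        return {
            "tp": self.counts.tp, "fp": self.counts.fp, "fn": self.counts.fn,
            "precision": self.precision, "recall": self.recall,
            "ap_per_threshold": {float(k): float(v)
                                 for k, v in self.ap_per_threshold.items()},
            "mAP@0.5": self.map50, "mAP@0.5:0.95": self.map50_95,
        }


def precision_recall(counts: ConfusionCounts) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); 0 by convention on empty denominators."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    return p, r


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float = 0.45,
        conf_thr: float = 0.0) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices into the input.

    Detections below ``conf_thr`` are discarded first. Suppression is in
    descending score order with stable tie-breaking (equal scores keep the
    earlier index), removing any remaining box with IoU > ``iou_thr``
    against a kept box.
    """
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    keep_mask = scores >= conf_thr
    idx = np.flatnonzero(keep_mask)
    if idx.size == 0:
        return np.empty(0, dtype=int)
    order = idx[np.argsort(-scores[idx], kind="stable")]
    iou_m = pairwise_iou(boxes[order], boxes[order])
    kept: list[int] = []
    alive = np.ones(len(order), dtype=bool)
    for i in range(len(order)):
        if not alive[i]:
            continue
        kept.append(order[i])
        alive[i + 1:] &= iou_m[i, i + 1:] <= iou_thr
    return np.array(kept, dtype=int)


def match_detections(det_boxes: np.ndarray, det_scores: np.ndarray,
                     gt_boxes: np.ndarray, iou_thr: float = 0.5) -> np.ndarray:
    """Greedy one-to-one matching for a single image.

    Returns a boolean TP flag per detection, in the input order.
    Detections are visited in descending score order; each claims its
    highest-IoU unmatched ground truth at or above ``iou_thr``. Equal
    scores are broken by the detection's best IoU against any ground truth,
    so the result does not depend on storage order.
    """
    det_boxes = np.asarray(det_boxes, dtype=np.float64).reshape(-1, 4)
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    tp = np.zeros(len(det_boxes), dtype=bool)
    if len(det_boxes) == 0 or len(gt_boxes) == 0:
        return tp
    iou_all = pairwise_iou(det_boxes, gt_boxes)
    best = iou_all.max(axis=1)
    order = np.lexsort((-best, -np.asarray(det_scores)))
    taken = np.zeros(len(gt_boxes), dtype=bool)
    for d in order:
        cand = np.where(~taken, iou_all[d], -1.0)
        j = int(cand.argmax())
        if cand[j] >= iou_thr:
            tp[d] = True
            taken[j] = True
    return tp


def _interp_ap(recall: np.ndarray, precision: np.ndarray) -> float:
    """101-point interpolated area under the precision-recall curve.

    At each recall level r in {0, 0.01, ..., 1} the interpolated precision
    is the maximum precision attained at any score cut whose recall is >= r
    (0 if none); AP is the mean over levels.
    """
    suffmax = np.maximum.accumulate(precision[::-1])[::-1]
    levels = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(recall, levels, side="left")
    vals = np.where(idx < len(recall), suffmax[np.minimum(idx, len(recall) - 1)], 0.0)
    return float(vals.mean())


def average_precision(detections: list[tuple[np.ndarray, np.ndarray]],
                      ground_truths: list[np.ndarray],
                      iou_thresholds=COCO_IOU_THRESHOLDS,
                      conf_thr: float = 0.25) -> MetricsReport:
    """Evaluate ranked detections against ground truth over a set of images.

    ``detections[i]`` is a ``(boxes, scores)`` pair for image i and
    ``ground_truths[i]`` its (M, 4) ground-truth boxes. The reported
    precision/recall and confusion counts are computed at IoU 0.5 using only
    detections with score >= ``conf_thr``; APs use every detection.
    """
    if len(detections) != len(ground_truths):
        raise ValueError("detections and ground truths must cover the same images")
    n_gt = int(sum(len(np.asarray(g).reshape(-1, 4)) for g in ground_truths))
    aps: dict[float, float] = {}
    import warnings
    if n_gt == 0:
        warnings.warn("no ground-truth boxes: AP undefined, reporting 0")
    for thr in iou_thresholds:
        scores_all = []
        tp_all = []
        for (boxes, scores), gts in zip(detections, ground_truths):
            tp = match_detections(boxes, scores, gts, float(thr))
            scores_all.append(np.asarray(scores, dtype=np.float64).reshape(-1))
            tp_all.append(tp)
        scores_all = np.concatenate(scores_all) if scores_all else np.empty(0)
        tp_all = np.concatenate(tp_all) if tp_all else np.empty(0, bool)
        if n_gt == 0 or scores_all.size == 0:
            aps[float(thr)] = 0.0
            continue
        order = np.argsort(-scores_all, kind="stable")
        tp_sorted = tp_all[order].astype(np.float64)
        cum_tp = np.cumsum(tp_sorted)
        cum_fp = np.cumsum(1.0 - tp_sorted)
        # a score cut cannot split tied scores: keep only the last entry of
        # each tie group, which also makes AP independent of storage order
        s_sorted = scores_all[order]
        last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
        recall = cum_tp[last] / n_gt
        precision = cum_tp[last] / np.maximum(cum_tp[last] + cum_fp[last], 1e-12)
        aps[float(thr)] = _interp_ap(recall, precision)

    # confusion counts at IoU 0.5 and the working confidence threshold
    tp_c = fp_c = 0
    for (boxes, scores), gts in zip(detections, ground_truths):
        scores = np.asarray(scores, dtype=np.float64).reshape(-1)
        mask = scores >= conf_thr
        boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)[mask]
        tp = match_detections(boxes, scores[mask], gts, 0.5)
        tp_c += int(tp.sum())
        fp_c += int((~tp).sum())
    counts = ConfusionCounts(tp=tp_c, fp=fp_c, fn=max(n_gt - tp_c, 0))
    p, r = precision_recall(counts)
    map50 = aps.get(0.5, 0.0)
    map5095 = float(np.mean(list(aps.values()))) if aps else 0.0
    return MetricsReport(counts=counts, precision=p, recall=r,
                         ap_per_threshold=aps, map50=map50, map50_95=map5095)
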