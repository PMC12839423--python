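"""Detection evaluation: matching, precision/recall/F1, AP and mAP.

Definitions::

    Precision = TP / (TP + FP)        Recall = TP / (TP + FN)
    F1 = 2 P R / (P + R)
    AP  = sum_i (r_{i+1} - r_i) * P_inter(r_{i+1})     (all-point interpolation)
    mAP = mean over classes;  mAP@50-95 additionally averages AP over IoU
          thresholds 0.50:0.05:0.95.

Matching is greedy one-to-one in descending confidence (ties broken by
detection id, ascending, for determinism): a detection is a true positive
iff its best-IoU unmatched same-class ground truth reaches the threshold.
Degenerate ratios (zero denominators) evaluate to 0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MatchCounts",
    "PRCurve",
    "box_iou_matrix",
    "match",
    "precision_recall_f1",
    "pr_curve",
    "average_precision",
    "mean_ap",
    "evaluate_detections",
    "IOU_THRESHOLDS_50_95",
]

IOU_THRESHOLDS_50_95 = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class MatchCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class PRCurve:
    """Recall points with all-point-interpolated precision at each."""

    recall: np.ndarray
    precision_interp: np.ndarray

    def __post_init__(self):
        r, p = np.asarray(self.recall), np.asarray(self.precision_interp)
        if r.shape != p.shape:
            raise ValueError("recall/precision length mismatch")
        if np.any(np.diff(r) < -1e-12):
            raise ValueError("recall points must be non-decreasing")


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of (N, 4) and (M, 4) boxes in cx, cy, w, h form."""
    a, b = np.atleast_2d(np.asarray(a, float)), np.atleast_2d(np.asarray(b, float))
    ax1, ay1 = a[:, 0] - a[:, 2] / 2, a[:, 1] - a[:, 3] / 2
    ax2, ay2 = a[:, 0] + a[:, 2] / 2, a[:, 1] + a[:, 3] / 2
    bx1, by1 = b[:, 0] - b[:, 2] / 2, b[:, 1] - b[:, 3] / 2
    bx2, by2 = b[:, 0] + b[:, 2] / 2, b[:, 1] + b[:, 3] / 2
    iw = np.clip(np.minimum(ax2[:, None], bx2) - np.maximum(ax1[:, None], bx1), 0, None)
    ih = np.clip(np.minimum(ay2[:, None], by2) - np.maximum(ay1[:, None], by1), 0, None)
    inter = iw * ih
    union = (a[:, 2] * a[:, 3])[:, None] + b[:, 2] * b[:, 3] - inter
    return inter / np.maximum(union, 1e-12)


def _greedy_tp_flags(dets: np.ndarray, gts: np.ndarray, iou_threshold: float
                     ) -> np.ndarray:
    """TP flag per detection row [class, conf, cx, cy, w, h] within one image."""
    dets = np.atleast_2d(np.asarray(dets, float))
    gts = np.atleast_2d(np.asarray(gts, float))
    flags = np.zeros(len(dets), dtype=bool)
    if len(dets) == 0 or len(gts) == 0:
        return flags
    order = np.lexsort((np.arange(len(dets)), -dets[:, 1]))  # conf desc, id asc
    iou = box_iou_matrix(dets[:, 2:6], gts[:, 1:5])
    taken = np.zeros(len(gts), dtype=bool)
    for di in order:
        same = (gts[:, 0] == dets[di, 0]) & ~taken
        if not same.any():
            continue
        cand = np.where(same)[0]
        best = cand[np.argmax(iou[di, cand])]
        if iou[di, best] >= iou_threshold:
            flags[di] = True
            taken[best] = True
    return flags


def match(dets: np.ndarray, gts: np.ndarray, iou_threshold: float = 0.5
          ) -> MatchCounts:
    """Greedy one-to-one matching of one image's detections to ground truth.

    ``dets``: (N, 6) rows [class, confidence, cx, cy, w, h];
    ``gts``: (M, 5) rows [class, cx, cy, w, h]. Units must agree.
    """
    dets = np.zeros((0, 6)) if len(dets) == 0 else np.atleast_2d(np.asarray(dets, float))
    gts = np.zeros((0, 5)) if len(gts) == 0 else np.atleast_2d(np.asarray(gts, float))
    flags = _greedy_tp_flags(dets, gts, iou_threshold)
    tp = int(flags.sum())
    return MatchCounts(tp=tp, fp=len(dets) - tp, fn=len(gts) - tp)


def precision_recall_f1(counts: MatchCounts) -> tuple[float, float, float]:
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fp == 0:
        warnings.warn("no detections: precision defined as 0", stacklevel=2)
        p = 0.0
    else:
        p = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no ground truth: recall defined as 0", stacklevel=2)
        r = 0.0
    else:
        r = tp / (tp + fn)
    f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return p, r, f1


def pr_curve(confidences: np.ndarray, tp_flags: np.ndarray, n_gt: int) -> PRCurve:
    """Precision-recall curve from per-detection TP flags (one class).

    Detections are ordered by (confidence desc, id asc); interpolated
    precision at each recall is the running maximum from the right.
    """
    if n_gt <= 0:
        raise ValueError("average precision is undefined without ground truth")
    confidences = np.asarray(confidences, float)
    tp_flags = np.asarray(tp_flags, bool)
    order = np.lexsort((np.arange(len(confidences)), -confidences))
    tp = np.cumsum(tp_flags[order])
    fp = np.cumsum(~tp_flags[order])
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    p_interp = np.maximum.accumulate(precision[::-1])[::-1] if len(precision) else precision
    return PRCurve(recall=recall, precision_interp=p_interp)


def average_precision(curve: PRCurve) -> float:
    """All-point interpolated area: sum over (r_{i+1}-r_i) * P_inter(r_{i+1})."""
    r = np.concatenate([[0.0], curve.recall])
    p = np.asarray(curve.precision_interp)
    if len(p) == 0:
        return 0.0
    return float(np.sum(np.diff(r) * p))


def mean_ap(per_class_ap: Mapping[int, float | None]) -> float:
    """Arithmetic mean of per-class AP; classes without AP are excluded."""
    vals = []
    for cid, ap in per_class_ap.items():
        if ap is None:
            warnings.warn(f"class {cid} has no ground truth; excluded from mAP",
                          stacklevel=2)
        else:
            vals.append(ap)
    if not vals:
        raise ValueError("no class has ground truth")
    return float(np.mean(vals))


def _class_ap(dets_by_image: Mapping, gts_by_image: Mapping, class_id: int,
              iou_threshold: float) -> float | None:
    confs, flags = [], []
    n_gt = 0
    for img in sorted(set(dets_by_image) | set(gts_by_image), key=str):
        d = np.atleast_2d(np.asarray(dets_by_image.get(img, np.zeros((0, 6))), float))
        g = np.atleast_2d(np.asarray(gts_by_image.get(img, np.zeros((0, 5))), float))
        d = d[d[:, 0] == class_id] if d.size else np.zeros((0, 6))
        g = g[g[:, 0] == class_id] if g.size else np.zeros((0, 5))
        n_gt += len(g)
        if len(d):
            confs.append(d[:, 1])
            flags.append(_greedy_tp_flags(d, g, iou_threshold))
    if n_gt == 0:
        return None
    if not confs:
        return 0.0
    curve = pr_curve(np.concatenate(confs), np.concatenate(flags), n_gt)
    return average_precision(curve)


def evaluate_detections(dets_by_image: Mapping, gts_by_image: Mapping,
                        class_ids: Sequence[int],
                        iou_threshold: float = 0.5,
                        thresholds_50_95: Sequence[float] = IOU_THRESHOLDS_50_95
                        ) -> dict:
    """Dataset-level summary: per-class AP@threshold, mAP@50 and mAP@50-95.

    Inputs are mappings image id -> detection array (N, 6) and ground-truth
    array (M, 5) in the row conventions of :func:`match`.
    """
    per_class = {c: _class_ap(dets_by_image, gts_by_image, c, iou_threshold)
                 for c in class_ids}
    result = {"per_class_ap": per_class, "map": mean_ap(per_class),
              "iou_threshold": iou_threshold}
    sweeps = []
    for thr in thresholds_50_95:
        aps = {c: _class_ap(dets_by_image, gts_by_image, c, thr) for c in class_ids}
        sweeps.append(mean_ap(aps))
    result["map_50_95"] = float(np.mean(sweeps))
    # aggregate counts at the primary threshold for P/R/F1
    tp = fp = fn = 0
    for img in sorted(set(dets_by_image) | set(gts_by_image), key=str):
        c = match(dets_by_image.get(img, np.zeros((0, 6))),
                  gts_by_image.get(img, np.zeros((0, 5))), iou_threshold)
        tp, fp, fn = tp + c.tp, fp + c.fp, fn + c.fn
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r, f1 = precision_recall_f1(MatchCounts(tp, fp, fn))
    result.update(precision=p, recall=r, f1=f1)
    return result
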