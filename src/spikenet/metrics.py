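"""Evaluation metrics for oriented spike detection.

Detection quality: greedy confidence-ordered matching against ground truth
at a rotated-IoU threshold (default 0.5), precision, recall, and all-point
average precision (area under the monotone precision envelope of the PR
curve).  Orientation quality: RMSE and MAE of *circular* angle differences
over true-positive pairs — angles live on a 180°-periodic axis, so the
difference between 179° and 1° is 2°, not 178°.  Counting quality: RMSE,
relative RMSE and MAE between per-image predicted and labeled spike counts.

Angle and counting errors are pooled over all pairs / images in a single
sum.  Degenerate conventions: precision := 0 when no detections, recall := 0
when no ground truth, AP := 0 with zero gt overall; angle errors on zero TP
pairs raise :class:`UndefinedMetricError`; a zero labeled count makes the
relative counting error NaN while the absolute errors are still returned.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .rotgeom import rotated_iou

__all__ = [
    "MatchResult",
    "EvalSummary",
    "UndefinedMetricError",
    "match",
    "precision_recall",
    "average_precision",
    "angle_errors",
    "counting_errors",
    "evaluate",
]


class UndefinedMetricError(ValueError):
    """The requested metric has no defined value on these inputs."""


def _pairs(dets):
    """Normalize detections to (box, confidence) tuples."""
    out = []
    for d in dets:
        if isinstance(d, tuple):
            out.append((d[0], float(d[1])))
        else:
            out.append((d.box, float(d.confidence)))
    return out


@dataclass
class MatchResult:
    """Per-image matching outcome.

    ``tp[i]`` lists (detection index, gt index, rotated IoU) pairs for image
    i; ``fp[i]`` / ``fn[i]`` list unmatched detection / gt indices.
    """

    tp: list
    fp: list
    fn: list

    @property
    def n_tp(self) -> int:
        return sum(len(t) for t in self.tp)

    @property
    def n_fp(self) -> int:
        return sum(len(f) for f in self.fp)

    @property
    def n_fn(self) -> int:
        return sum(len(f) for f in self.fn)


def match(dets_per_image, gts_per_image, iou_threshold: float = 0.5) -> MatchResult:
    """Greedy matching in descending confidence (ties broken by smaller
    detection index).  A detection is TP iff its best-IoU still-unmatched gt
    reaches the threshold; each gt matches at most once."""
    tp, fp, fn = [], [], []
    for dets, gts in zip(dets_per_image, gts_per_image):
        pairs = _pairs(dets)
        order = sorted(range(len(pairs)), key=lambda i: -pairs[i][1])
        taken = set()
        img_tp, img_fp = [], []
        for i in order:
            box = pairs[i][0]
            best_iou, best_j = 0.0, -1
            for j, g in enumerate(gts):
                if j in taken:
                    continue
                iou = rotated_iou(box, g)
                if iou > best_iou:
                    best_iou, best_j = iou, j
            if best_j >= 0 and best_iou >= iou_threshold:
                taken.add(best_j)
                img_tp.append((i, best_j, best_iou))
            else:
                img_fp.append(i)
        tp.append(img_tp)
        fp.append(img_fp)
        fn.append([j for j in range(len(gts)) if j not in taken])
    return MatchResult(tp=tp, fp=fp, fn=fn)


def precision_recall(m: MatchResult) -> tuple:
    tp, fp, fn = m.n_tp, m.n_fp, m.n_fn
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return precision, recall


def _pr_curve(dets_per_image, gts_per_image, iou_threshold: float):
    """Global confidence-ordered PR points (one per detection)."""
    n_gt = sum(len(g) for g in gts_per_image)
    flat = []
    for img, dets in enumerate(dets_per_image):
        for i, (box, conf) in enumerate(_pairs(dets)):
            flat.append((conf, img, i, box))
    # descending confidence; ties by (image, detection index) for determinism
    flat.sort(key=lambda t: (-t[0], t[1], t[2]))
    taken = [set() for _ in gts_per_image]
    tps = np.zeros(len(flat))
    for k, (_, img, _, box) in enumerate(flat):
        gts = gts_per_image[img]
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(gts):
            if j in taken[img]:
                continue
            iou = rotated_iou(box, g)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[img].add(best_j)
            tps[k] = 1.0
    cum_tp = np.cumsum(tps)
    cum_fp = np.cumsum(1.0 - tps)
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
    recall = cum_tp / n_gt if n_gt > 0 else np.zeros(len(flat))
    return precision, recall, n_gt


def average_precision(dets_per_image, gts_per_image, iou_threshold: float = 0.5) -> float:
    """All-point AP: exact area under the monotone precision envelope."""
    precision, recall, n_gt = _pr_curve(dets_per_image, gts_per_image, iou_threshold)
    if n_gt == 0 or len(precision) == 0:
        return 0.0
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[1.0], precision])
    # monotone non-increasing envelope from the right
    p = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum((r[1:] - r[:-1]) * p[1:]))


def circular_angle_diff(a: float, b: float) -> float:
    """Difference of two long-side angles on the 180°-periodic axis."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def angle_errors(m: MatchResult, dets_per_image, gts_per_image) -> tuple:
    """(RMSE, MAE) in degrees of circular angle differences over TP pairs,
    pooled across images."""
    diffs = []
    for img, img_tp in enumerate(m.tp):
        pairs = _pairs(dets_per_image[img])
        gts = gts_per_image[img]
        for det_i, gt_j, _ in img_tp:
            diffs.append(circular_angle_diff(pairs[det_i][0].theta_deg, gts[gt_j].theta_deg))
    if not diffs:
        raise UndefinedMetricError("angle errors undefined with zero true-positive pairs")
    d = np.asarray(diffs)
    return float(np.sqrt(np.mean(d**2))), float(np.mean(np.abs(d)))


def counting_errors(pred_counts, true_counts) -> tuple:
    """(RMSE, rRMSE, MAE) between per-image predicted and labeled counts.

    rRMSE normalizes each term by the labeled count and is NaN if any image
    has a zero labeled count (the absolute errors are still returned)."""
    t = np.asarray(pred_counts, dtype=float)
    a = np.asarray(true_counts, dtype=float)
    if t.shape != a.shape:
        raise ValueError(f"count lists differ in length: {t.shape} vs {a.shape}")
    err = a - t
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.any(a == 0):
        rrmse = math.nan
    else:
        rrmse = float(np.sqrt(np.mean((err / a) ** 2)))
    return rmse, rrmse, mae


@dataclass
class EvalSummary:
    precision: float
    recall: float
    ap: float
    rmse_z: float
    mae_z: float
    rmse_c: float
    rrmse_c: float
    mae_c: float
    n_images: int
    n_gt: int
    n_detections: int
    iou_threshold: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def report(self) -> str:
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        return "\n".join(lines)


def evaluate(dets_per_image, gts_per_image, iou_threshold: float = 0.5) -> EvalSummary:
    """Full evaluation of a detection run (detection, angle and counting)."""
    if len(dets_per_image) != len(gts_per_image):
        raise ValueError("detections and ground truth cover different image sets")
    m = match(dets_per_image, gts_per_image, iou_threshold)
    precision, recall = precision_recall(m)
    ap = average_precision(dets_per_image, gts_per_image, iou_threshold)
    try:
        rmse_z, mae_z = angle_errors(m, dets_per_image, gts_per_image)
    except UndefinedMetricError:
        rmse_z = mae_z = math.nan
    rmse_c, rrmse_c, mae_c = counting_errors(
        [len(d) for d in dets_per_image], [len(g) for g in gts_per_image])
    return EvalSummary(
        precision=precision, recall=recall, ap=ap,
        rmse_z=rmse_z, mae_z=mae_z,
        rmse_c=rmse_c, rrmse_c=rrmse_c, mae_c=mae_c,
        n_images=len(gts_per_image),
        n_gt=sum(len(g) for g in gts_per_image),
        n_detections=sum(len(d) for d in dets_per_image),
        iou_threshold=iou_threshold,
    )
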