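"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
import shapely

from spikenet.rotgeom import OrientedBox, to_polygon


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_box(rng, span=100.0, long_range=(8.0, 40.0), aspect_range=(1.0, 5.0),
               margin=25.0) -> OrientedBox:
    h = rng.uniform(*long_range)
    w = h / rng.uniform(*aspect_range)
    return OrientedBox(
        rng.uniform(margin, span - margin), rng.uniform(margin, span - margin),
        w, h, rng.uniform(0.0, 180.0))


def point_in_box(box: OrientedBox, x, y):
    """Vectorized membership test via rotation into the box frame."""
    t = np.radians(box.theta_deg)
    dx, dy = np.asarray(x) - box.cx, np.asarray(y) - box.cy
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    return (np.abs(u) <= box.h / 2) & (np.abs(v) <= box.w / 2)


def monte_carlo_iou(a: OrientedBox, b: OrientedBox, n: int, rng) -> float:
    """Rasterization-free Monte-Carlo IoU oracle: sample uniformly over the
    joint bounding box and count membership in each rectangle."""
    corners = np.vstack([to_polygon(a), to_polygon(b)])
    lo, hi = corners.min(axis=0), corners.max(axis=0)
    x = rng.uniform(lo[0], hi[0], n)
    y = rng.uniform(lo[1], hi[1], n)
    in_a = point_in_box(a, x, y)
    in_b = point_in_box(b, x, y)
    union = np.count_nonzero(in_a | in_b)
    if union == 0:
        return 0.0
    return np.count_nonzero(in_a & in_b) / union


def rasterize_boxes(boxes, size: int) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside any box (the pixel
    at (r, c) has center (c + 0.5, r + 0.5))."""
    ys, xs = np.mgrid[0:size, 0:size]
    mask = np.zeros((size, size), dtype=bool)
    for b in boxes:
        poly = shapely.polygons(to_polygon(b))
        mask |= shapely.contains_xy(poly, xs + 0.5, ys + 0.5)
    return mask


def greedy_nms_oracle(dets, thr):
    """Independent brute-force greedy suppression over all pairs."""
    from spikenet.rotgeom import rotated_iou

    idx = sorted(range(len(dets)), key=lambda i: (-dets[i][1], i))
    keep, suppressed = [], set()
    for i in idx:
        if i in suppressed:
            continue
        keep.append(i)
        for j in idx:
            if j != i and j not in suppressed:
                if rotated_iou(dets[i][0], dets[j][0]) > thr:
                    suppressed.add(j)
    return [dets[i] for i in keep]


def ap_threshold_sweep_oracle(dets_per_image, gts_per_image, iou_thr) -> float:
    """Exhaustive confidence-threshold sweep + monotone-envelope integration,
    independent of the package's cumulative-count implementation."""
    from spikenet.metrics import match

    confs = sorted({c for dd in dets_per_image for _, c in dd}, reverse=True)
    n_gt = sum(len(g) for g in gts_per_image)
    if n_gt == 0:
        return 0.0
    points = []
    for c in confs:
        filt = [[(b, cc) for b, cc in dd if cc >= c] for dd in dets_per_image]
        m = match(filt, gts_per_image, iou_thr)
        tp, fp = m.n_tp, m.n_fp
        points.append((tp / n_gt, tp / max(tp + fp, 1)))
    points.sort()
    ap, prev_r = 0.0, 0.0
    for k, (r, _) in enumerate(points):
        p_env = max(p for _, p in points[k:])
        ap += (r - prev_r) * p_env
        prev_r = r
    return ap


def targets_to_logits(preds, targets, csl_cfg, anchors, saturate: float = 12.0):
    """Overwrite raw prediction arrays with logits that exactly encode the
    assigned targets (inverse of the decode transforms); used for
    encode->decode round-trip checks."""
    for l, (gp, tgt) in enumerate(zip(preds, targets)):
        n, c, h, w = gp.data.shape
        p = gp.data.data.reshape(n, gp.na, 6 + gp.K, h, w)
        p[:] = 0.0
        p[:, :, 4] = -saturate                       # objectness off everywhere
        if tgt.n == 0:
            continue
        def inv_sig(s):
            s = np.clip(s, 1e-6, 1 - 1e-6)
            return np.log(s / (1 - s))
        toff_s = (tgt.toff + 0.5) / 2.0
        wh_s = np.sqrt(tgt.wh / anchors.anchors[l][tgt.anchor]) / 2.0
        for m in range(tgt.n):
            i, a, gy, gx = tgt.img[m], tgt.anchor[m], tgt.gy[m], tgt.gx[m]
            p[i, a, 0, gy, gx] = inv_sig(toff_s[m, 0])
            p[i, a, 1, gy, gx] = inv_sig(toff_s[m, 1])
            p[i, a, 2, gy, gx] = inv_sig(wh_s[m, 0])
            p[i, a, 3, gy, gx] = inv_sig(wh_s[m, 1])
            p[i, a, 4, gy, gx] = saturate
            p[i, a, 5, gy, gx] = saturate
            # soft CSL scores as logits: argmax still decodes the true bin
            p[i, a, 6:, gy, gx] = inv_sig(tgt.csl[m])
    return preds
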