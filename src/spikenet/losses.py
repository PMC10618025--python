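"""Multi-task training loss: CIoU localization, BCE objectness/class, and
BCE over circular-smooth-label angle targets.

The localization term is evaluated in the ground-truth box's rotated frame:
the predicted geometry (center offset, sides) and the gt rectangle share the
gt angle there, so the IoU term reduces to an axis-aligned intersection and
the whole CIoU expression stays differentiable; the orientation itself is
learned by the separate CSL classification branch.  The objectness target at
assigned positions is the (detached) rotated IoU between the decoded
predicted box — with its angle taken from the current CSL argmax — and the
ground truth, following the convention that confidence should predict
localization quality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .rotgeom import rotated_iou_batch

__all__ = ["LossWeights", "LossBreakdown", "compute_loss", "ciou_aligned"]

# per-layer objectness balance, stride 4 -> 32; counteracts grid-size imbalance
OBJ_BALANCE = {4: (4.0, 1.0, 0.4, 0.1), 3: (4.0, 1.0, 0.4)}


@dataclass(frozen=True)
class LossWeights:
    localization: float = 0.05
    objectness: float = 1.0
    classification: float = 0.5
    angle: float = 0.5


@dataclass
class LossBreakdown:
    total: nn.Tensor                 # scalar tensor, call .backward() on it
    localization: float
    objectness: float
    classification: float
    angle: float
    weights: LossWeights

    def check(self, tol: float = 1e-5) -> bool:
        w = self.weights
        s = (w.localization * self.localization + w.objectness * self.objectness
             + w.classification * self.classification + w.angle * self.angle)
        return abs(s - float(self.total.data)) <= tol * max(1.0, abs(s))


def ciou_aligned(pxy, pwh, gwh, use_ciou: bool = True):
    """Differentiable CIoU between predicted and gt boxes sharing one angle.

    ``pxy`` (M, 2): predicted center offset from the gt center, already
    rotated into the gt frame (pixels), whose +x axis is the gt *long* axis;
    ``pwh``/``gwh`` (M, 2): (short, long) sides in pixels, so the x-extent of
    each box in this frame is its long side and the y-extent its short side.
    Returns a length-M tensor of per-position losses; with
    ``use_ciou=False`` only ``1 - IoU``.
    """
    px, py = pxy[:, 0], pxy[:, 1]
    pw, ph = pwh[:, 0], pwh[:, 1]
    gwh = np.asarray(gwh, dtype=float)
    gw, gh = nn.Tensor(gwh[:, 0]), nn.Tensor(gwh[:, 1])
    half = 0.5
    inter_x = (px + ph * half).minimum(gh * half) - (px - ph * half).maximum(gh * (-half))
    inter_y = (py + pw * half).minimum(gw * half) - (py - pw * half).maximum(gw * (-half))
    inter = inter_x.relu() * inter_y.relu()
    union = pw * ph + gw * gh - inter + 1e-9
    iou = inter / union
    if not use_ciou:
        return 1.0 - iou
    dist2 = px**2 + py**2
    enc_x = (px + ph * half).maximum(gh * half) - (px - ph * half).minimum(gh * (-half))
    enc_y = (py + pw * half).maximum(gw * half) - (py - pw * half).minimum(gw * (-half))
    diag2 = enc_x**2 + enc_y**2 + 1e-9
    # aspect term on (short, long) pairs; predictions may transiently have
    # pw > ph, so order the sides explicitly
    v = (4.0 / math.pi**2) * (
        (pw.minimum(ph) / pw.maximum(ph)).arctan() - (gw / gh).arctan()) ** 2
    gamma = v**2 / ((1.0 - iou) + v + 1e-9)
    return 1.0 - iou + dist2 / diag2 + gamma


def compute_loss(preds, targets, anchors, csl_cfg,
                 weights: LossWeights = LossWeights(),
                 use_ciou: bool = True) -> LossBreakdown:
    """Total training loss over one batch.

    ``preds`` is the list of :class:`GridPrediction` from the detector and
    ``targets`` the matching list of :class:`LayerTargets`.  Localization,
    class and angle terms average over assigned positions; objectness is a
    per-layer-balanced BCE over *all* positions with detached-rotated-IoU
    targets at the assigned ones.  With no assignments anywhere, only the
    objectness term is non-trivial.
    """
    balance = OBJ_BALANCE[len(preds)]
    zero = nn.Tensor(np.zeros(()))
    loc_terms, ang_terms, cls_terms = [], [], []
    obj_total = zero
    n_assigned = 0
    for l, (gp, tgt) in enumerate(zip(preds, targets)):
        p = gp.reshaped()                      # (N, na, 6+K, H, W)
        n, na, _, h, w = p.shape
        obj_target = np.zeros((n, na, h, w), dtype=np.float32)
        if tgt.n > 0:
            n_assigned += tgt.n
            sel = p[tgt.img, tgt.anchor, :, tgt.gy, tgt.gx]   # (M, 6+K)
            txy = 2.0 * sel[:, 0:2].sigmoid() - 0.5           # cell units
            layer_anchors = anchors.anchors[l][tgt.anchor]      # (M, 2)
            pwh = (2.0 * sel[:, 2:4].sigmoid()) ** 2 * nn.Tensor(layer_anchors)
            # center offset from gt center in pixels, rotated into gt frame
            off_px = (txy - nn.Tensor(tgt.toff)) * float(gp.stride)
            ct = np.cos(np.radians(tgt.theta))
            st = np.sin(np.radians(tgt.theta))
            dx, dy = off_px[:, 0], off_px[:, 1]
            rx = dx * ct + dy * st
            ry = dx * (-st) + dy * ct
            pxy = nn.concat([rx.reshape(-1, 1), ry.reshape(-1, 1)], axis=1)
            ciou = ciou_aligned(pxy, pwh, tgt.wh, use_ciou=use_ciou)
            loc_terms.append(ciou)
            ang_terms.append(nn.bce_with_logits(sel[:, 6:], tgt.csl).mean(axis=-1))
            cls_terms.append(nn.bce_with_logits(sel[:, 5], np.ones(tgt.n, dtype=np.float32)))
            obj_target[tgt.img, tgt.anchor, tgt.gy, tgt.gx] = _detached_iou_targets(
                gp, tgt, txy.data, pwh.data, csl_cfg, sel.data)
        obj_bce = nn.bce_with_logits(p[:, :, 4], obj_target).mean()
        obj_total = obj_total + obj_bce * balance[l]
    obj = obj_total * (1.0 / len(preds))
    if n_assigned:
        loc = nn.concat(loc_terms).mean()
        ang = nn.concat(ang_terms).mean()
        cls = nn.concat(cls_terms).mean()
    else:
        loc = ang = cls = zero
    total = (loc * weights.localization + obj * weights.objectness
             + cls * weights.classification + ang * weights.angle)
    return LossBreakdown(
        total=total,
        localization=float(loc.data), objectness=float(obj.data),
        classification=float(cls.data), angle=float(ang.data), weights=weights)


def _detached_iou_targets(gp, tgt, txy, pwh, csl_cfg, sel) -> np.ndarray:
    """Rotated IoU between the decoded predicted box (angle from the current
    CSL argmax) and its gt, clipped to [0, 1]; no gradient flows through."""
    cx = (txy[:, 0] + tgt.gx) * gp.stride
    cy = (txy[:, 1] + tgt.gy) * gp.stride
    theta = np.argmax(sel[:, 6:], axis=1) * (180.0 / csl_cfg.K)
    pred = np.stack([cx, cy, pwh[:, 0], pwh[:, 1], theta], axis=1)
    gt = np.stack([
        [b.cx for b in tgt.boxes], [b.cy for b in tgt.boxes],
        tgt.wh[:, 0], tgt.wh[:, 1], tgt.theta], axis=1)
    return np.clip(rotated_iou_batch(pred, gt), 0.0, 1.0).astype(np.float32)
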