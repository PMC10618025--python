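"""Oriented-box geometry: data model, rotated IoU, CIoU, rotated NMS.

A spike annotation or prediction is an oriented rectangle parameterized by
center, short/long side lengths and the angle of the *long* side measured
from the +x axis toward +y (image coordinates, y down), in degrees in
``[0, 180)``.  This gives each physical rectangle a unique representative
(up to the ``w == h`` square degeneracy, where the stored angle is kept
as-is).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "InvalidBoxError",
    "OrientedBox",
    "to_polygon",
    "polygon_to_box",
    "rotated_iou",
    "ciou_loss",
    "rotated_nms",
    "read_boxes",
    "write_boxes",
]


class InvalidBoxError(ValueError):
    """Raised for degenerate or malformed oriented boxes."""


def normalize_angle(theta_deg: float) -> float:
    """Reduce an angle to the canonical long-side range [0, 180)."""
    t = float(theta_deg) % 180.0
    return 0.0 if t == 180.0 else t


@dataclass(frozen=True)
class OrientedBox:
    """Oriented rectangle: center (cx, cy), short side w, long side h,
    long-side angle ``theta_deg`` in [0, 180), class label ``cls``."""

    cx: float
    cy: float
    w: float
    h: float
    theta_deg: float
    cls: str = "spike"

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(f"non-positive sides: w={self.w}, h={self.h}")
        if self.w > self.h + 1e-9:
            raise InvalidBoxError(f"short side exceeds long side: w={self.w} > h={self.h}")
        object.__setattr__(self, "theta_deg", normalize_angle(self.theta_deg))

    @classmethod
    def from_sides(cls, cx, cy, side_a, side_b, angle_a_deg, label="spike") -> "OrientedBox":
        """Build a box from two sides where ``side_a`` lies along
        ``angle_a_deg``; swaps sides (rotating the angle by 90°) so that the
        stored angle is the long-side angle and ``w <= h``."""
        if side_a >= side_b:
            return cls(cx, cy, side_b, side_a, angle_a_deg, label)
        return cls(cx, cy, side_a, side_b, angle_a_deg + 90.0, label)

    @property
    def area(self) -> float:
        return self.w * self.h


def to_polygon(box: OrientedBox) -> np.ndarray:
    """Corner polygon of the box: (4, 2) array in consistent winding order."""
    t = math.radians(box.theta_deg)
    ux, uy = math.cos(t), math.sin(t)          # long-side direction
    vx, vy = -uy, ux                           # short-side direction
    hh, hw = box.h / 2.0, box.w / 2.0
    c = np.array([box.cx, box.cy])
    return np.array([
        c + [-hh * ux - hw * vx, -hh * uy - hw * vy],
        c + [hh * ux - hw * vx, hh * uy - hw * vy],
        c + [hh * ux + hw * vx, hh * uy + hw * vy],
        c + [-hh * ux + hw * vx, -hh * uy + hw * vy],
    ])


def polygon_to_box(poly: np.ndarray, label: str = "spike") -> OrientedBox:
    """Inverse of :func:`to_polygon` for rectangle corner arrays."""
    p = np.asarray(poly, dtype=float)
    if p.shape != (4, 2):
        raise InvalidBoxError(f"expected 4 corner points, got shape {p.shape}")
    c = p.mean(axis=0)
    e1 = p[1] - p[0]
    e2 = p[3] - p[0]
    a, b = float(np.linalg.norm(e1)), float(np.linalg.norm(e2))
    if a >= b:
        ang = math.degrees(math.atan2(e1[1], e1[0]))
        return OrientedBox(c[0], c[1], b, a, ang, label)
    ang = math.degrees(math.atan2(e2[1], e2[0]))
    return OrientedBox(c[0], c[1], a, b, ang, label)


def _shapely(box: OrientedBox) -> Polygon:
    return Polygon(to_polygon(box))


def rotated_iou(a: OrientedBox, b: OrientedBox) -> float:
    """Intersection-over-union of two oriented rectangles (convex clip)."""
    pa, pb = _shapely(a), _shapely(b)
    inter = pa.intersection(pb).area
    if inter <= 0.0:
        return 0.0
    union = pa.area + pb.area - inter
    return float(inter / union)


def corners_batch(params: np.ndarray) -> np.ndarray:
    """Corner polygons for (M, 5) box parameter rows (cx, cy, w, h, theta_deg).

    The w/h labelling does not matter here: the corner set is the same
    rectangle either way."""
    p = np.asarray(params, dtype=float)
    t = np.radians(p[:, 4])
    u = np.stack([np.cos(t), np.sin(t)], axis=1)       # along h
    v = np.stack([-u[:, 1], u[:, 0]], axis=1)          # along w
    c = p[:, :2]
    hu = u * (p[:, 3] / 2.0)[:, None]
    hv = v * (p[:, 2] / 2.0)[:, None]
    return np.stack([c - hu - hv, c + hu - hv, c + hu + hv, c - hu + hv], axis=1)


def rotated_iou_batch(params_a: np.ndarray, params_b: np.ndarray) -> np.ndarray:
    """Vectorized rotated IoU between paired (M, 5) parameter rows."""
    import shapely as _sh

    a = np.asarray(params_a, dtype=float)
    b = np.asarray(params_b, dtype=float)
    if len(a) == 0:
        return np.zeros(0)
    pa = _sh.polygons(corners_batch(a))
    pb = _sh.polygons(corners_batch(b))
    inter = _sh.area(_sh.intersection(pa, pb))
    union = a[:, 2] * a[:, 3] + b[:, 2] * b[:, 3] - inter
    return np.where(inter > 0, inter / np.maximum(union, 1e-12), 0.0)


def ciou_loss(anchor: OrientedBox, target: OrientedBox) -> float:
    """Complete-IoU loss between two oriented boxes.

    ``1 - IoU`` plus (i) the squared center distance normalized by the
    squared diagonal of the smallest axis-aligned rectangle enclosing both
    corner polygons and (ii) an aspect-ratio consistency term
    ``gamma = v^2 / ((1 - IoU) + v)`` with
    ``v = (4/pi^2) (arctan(w_t/h_t) - arctan(w_a/h_a))^2`` on the
    (short, long) side pairs.  Zero iff the two boxes coincide.
    """
    iou = rotated_iou(anchor, target)
    dist2 = (anchor.cx - target.cx) ** 2 + (anchor.cy - target.cy) ** 2
    corners = np.vstack([to_polygon(anchor), to_polygon(target)])
    span = corners.max(axis=0) - corners.min(axis=0)
    diag2 = float(span[0] ** 2 + span[1] ** 2)
    v = (4.0 / math.pi**2) * (
        math.atan(target.w / target.h) - math.atan(anchor.w / anchor.h)
    ) ** 2
    gamma = 0.0 if v == 0.0 else v**2 / ((1.0 - iou) + v)
    return float(1.0 - iou + dist2 / diag2 + gamma)


def rotated_nms(dets, iou_threshold: float):
    """Greedy rotated non-maximum suppression.

    ``dets`` is a sequence of ``(OrientedBox, confidence)``; returns the
    retained pairs sorted by descending confidence.  Ties in confidence are
    broken by the smaller input index (stable sort), so the result is
    deterministic.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i][1])
    kept: list[int] = []
    for i in order:
        box = dets[i][0]
        if all(rotated_iou(box, dets[j][0]) <= iou_threshold for j in kept):
            kept.append(i)
    return [dets[i] for i in kept]


# ---------------------------------------------------------------------------
# Plain-text exchange format: one box per line,
#   cx cy w h theta_deg cls [confidence]
# whitespace-separated, UTF-8, '#' starts a comment.
# ---------------------------------------------------------------------------


def write_boxes(path, boxes, confidences=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# cx cy w h theta_deg cls [confidence]\n")
        for i, b in enumerate(boxes):
            line = f"{b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f} {b.theta_deg:.6f} {b.cls}"
            if confidences is not None:
                line += f" {confidences[i]:.6f}"
            fh.write(line + "\n")


def read_boxes(path):
    """Read the plain-text box format; returns (boxes, confidences).

    ``confidences`` is ``None`` if no line carried one.
    """
    boxes, confs = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (6, 7):
                raise InvalidBoxError(f"{path}:{lineno}: expected 6 or 7 fields, got {len(parts)}")
            cx, cy, w, h, th = (float(x) for x in parts[:5])
            boxes.append(OrientedBox(cx, cy, w, h, th, parts[5]))
            confs.append(float(parts[6]) if len(parts) == 7 else None)
    if all(c is None for c in confs):
        return boxes, None
    return boxes, [0.0 if c is None else c for c in confs]
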