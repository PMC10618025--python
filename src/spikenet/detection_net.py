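"""One-stage oriented spike detector.

A reduced CSP-style backbone with four down-sampling stages feeds an
FPN-style top-down neck with detection heads at strides 4, 8, 16 and 32.
The stride-4 *micro-scale* head (one-fourth of the input resolution) exists
specifically for very small spikes (long side under ~16 px) that coarser
grids cannot assign cleanly; it can be switched off to recover the standard
three-layer configuration for ablation.

Each head predicts, per cell and anchor: 4 box-regression values, an
objectness logit, a class logit (single "spike" class, kept for
architectural fidelity) and K angle-class logits decoded by the circular
smooth label scheme.  Box transforms follow the bounded convention
``center = (2 sigmoid(t) - 0.5 + cell) * stride`` and
``side = (2 sigmoid(t))^2 * anchor``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import csl as csl_mod
from . import nn
from .csl import CSLConfig
from .rotgeom import OrientedBox

__all__ = [
    "AnchorSet",
    "GridPrediction",
    "Detection",
    "LayerTargets",
    "DetectionNet",
    "default_anchors",
    "encode_targets",
    "decode",
    "InvalidAnnotationError",
]

ALL_STRIDES = (4, 8, 16, 32)


class InvalidAnnotationError(ValueError):
    pass


def default_anchors(strides=ALL_STRIDES) -> "AnchorSet":
    """Geometric (short, long) priors: base (6, 14) px at stride 4 doubling
    to (48, 112) px at stride 32, three scale variants per layer."""
    scales = (2 ** -0.5, 1.0, 2 ** 0.5)
    anchors = []
    for s in strides:
        base_w, base_h = 6.0 * s / 4.0, 14.0 * s / 4.0
        anchors.append([(base_w * k, base_h * k) for k in scales])
    return AnchorSet(strides=tuple(strides), anchors=np.asarray(anchors, dtype=float))


@dataclass(frozen=True)
class AnchorSet:
    """Per-layer (short, long) side priors in pixels: array (L, na, 2)."""

    strides: tuple
    anchors: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.anchors, dtype=float)
        if a.ndim != 3 or a.shape[0] != len(self.strides) or a.shape[2] != 2:
            raise ValueError(f"anchors must be (n_layers, na, 2), got {a.shape}")
        if np.any(a <= 0):
            raise ValueError("anchor sides must be positive")
        if np.any(a[..., 1] < a[..., 0]):
            raise ValueError("anchor long side must be >= short side")
        object.__setattr__(self, "anchors", a)

    @property
    def per_layer(self) -> int:
        return self.anchors.shape[1]


@dataclass
class GridPrediction:
    """Raw head output on a stride-s grid: tensor (N, na*(6+K), H, W) with
    per-anchor channel layout [tx, ty, tw, th, obj, cls, angle_0..angle_K-1]."""

    stride: int
    data: nn.Tensor
    na: int
    K: int

    def reshaped(self) -> nn.Tensor:
        n, c, h, w = self.data.shape
        return self.data.reshape(n, self.na, 6 + self.K, h, w)


@dataclass
class Detection:
    box: OrientedBox
    confidence: float
    angle_scores: np.ndarray = None


class _Bottleneck(nn.Module):
    def __init__(self, c: int, rng):
        self.conv1 = nn.ConvBnAct(c, c // 2, 1, rng=rng)
        self.conv2 = nn.ConvBnAct(c // 2, c, 3, rng=rng)

    def __call__(self, x):
        return self.conv2(self.conv1(x)) + x


class DetectionNet(nn.Module):
    """Backbone + FPN neck + per-stride prediction heads."""

    def __init__(self, K: int = 36, base_width: int = 16, neck_width: int = 32,
                 anchors: AnchorSet = None, micro_layer: bool = True,
                 rng: np.random.Generator = None):
        rng = rng or np.random.default_rng(0)
        self.K = K
        self.micro_layer = bool(micro_layer)
        self.strides = ALL_STRIDES if micro_layer else ALL_STRIDES[1:]
        self.anchors = anchors if anchors is not None else default_anchors(self.strides)
        if len(self.anchors.strides) != len(self.strides):
            raise ValueError(
                f"anchor set has {len(self.anchors.strides)} layers, model has {len(self.strides)}")
        na = self.anchors.per_layer
        b = base_width
        widths = {4: 2 * b, 8: 3 * b, 16: 4 * b, 32: 5 * b}
        self.down1 = nn.ConvBnAct(3, b, 3, stride=2, rng=rng)
        self.down2 = nn.ConvBnAct(b, widths[4], 3, stride=2, rng=rng)
        self.down3 = nn.ConvBnAct(widths[4], widths[8], 3, stride=2, rng=rng)
        self.block3 = _Bottleneck(widths[8], rng)
        self.down4 = nn.ConvBnAct(widths[8], widths[16], 3, stride=2, rng=rng)
        self.block4 = _Bottleneck(widths[16], rng)
        self.down5 = nn.ConvBnAct(widths[16], widths[32], 3, stride=2, rng=rng)
        self.block5 = _Bottleneck(widths[32], rng)
        self.laterals = [nn.ConvBnAct(widths[s], neck_width, 1, rng=rng, act=False)
                         for s in self.strides]
        self.smooths = [nn.ConvBnAct(neck_width, neck_width, 3, rng=rng)
                        for _ in self.strides[:-1]]
        self.heads = [nn.Conv2d(neck_width, na * (6 + K), 1, rng=rng) for _ in self.strides]
        for head in self.heads:
            # near-zero head init: predictions start at the bias priors
            head.weight.data *= 0.01
            # prior: rare objects -> strongly negative initial objectness
            head.bias.data.reshape(na, 6 + K)[:, 4] = -4.0

    def forward(self, img: nn.Tensor) -> list:
        n, c, h, w = img.shape
        if h % 32 or w % 32:
            raise ValueError(f"input spatial size must be divisible by 32, got {w}x{h}")
        x = self.down1(img)
        c2 = self.down2(x)
        c3 = self.block3(self.down3(c2))
        c4 = self.block4(self.down4(c3))
        c5 = self.block5(self.down5(c4))
        feats = {4: c2, 8: c3, 16: c4, 32: c5}
        laterals = [lat(feats[s]) for lat, s in zip(self.laterals, self.strides)]
        pyramid = [None] * len(self.strides)
        pyramid[-1] = laterals[-1]
        for i in range(len(self.strides) - 2, -1, -1):
            merged = laterals[i] + pyramid[i + 1].upsample2x()
            pyramid[i] = self.smooths[i](merged)
        na = self.anchors.per_layer
        return [GridPrediction(stride=s, data=head(p), na=na, K=self.K)
                for s, head, p in zip(self.strides, self.heads, pyramid)]

    __call__ = forward


# ---------------------------------------------------------------------------
# Target assignment (training) and prediction decoding (inference)
# ---------------------------------------------------------------------------


@dataclass
class LayerTargets:
    """Assigned positions for one detection layer (parallel arrays)."""

    stride: int
    grid: tuple                        # (H, W)
    img: np.ndarray                    # (M,) image index
    anchor: np.ndarray                 # (M,) anchor index
    gy: np.ndarray                     # (M,) cell row
    gx: np.ndarray                     # (M,) cell col
    toff: np.ndarray                   # (M, 2) center offset target, cell units
    wh: np.ndarray                     # (M, 2) gt (short, long) px
    theta: np.ndarray                  # (M,) gt long-side angle, deg
    csl: np.ndarray                    # (M, K) circular smooth label targets
    boxes: list                        # (M,) gt OrientedBox

    @property
    def n(self) -> int:
        return len(self.img)


def encode_targets(gts_per_image, anchors: AnchorSet, grid_shapes, img_size: int,
                   csl_cfg: CSLConfig, ratio_gate: float = 4.0) -> list:
    """Assign ground-truth boxes to (layer, cell, anchor) positions.

    A gt matches an anchor when both side ratios are below ``ratio_gate``;
    it is placed in its center cell plus up to two neighbor cells (the ones
    its center is closest to, YOLOv5 convention).  A gt matching no anchor
    anywhere falls back to the single best-ratio anchor so that every gt
    has at least one assignment.  Duplicate (layer, cell, anchor) slots keep
    the first assignment.
    """
    L = len(anchors.strides)
    acc = [{"img": [], "anchor": [], "gy": [], "gx": [], "toff": [], "wh": [],
            "theta": [], "csl": [], "boxes": []} for _ in range(L)]
    used = set()

    def put(l, i, a, cy, cx, gxf, gyf, b):
        key = (l, i, a, cy, cx)
        if key in used:
            return False
        used.add(key)
        acc[l]["img"].append(i)
        acc[l]["anchor"].append(a)
        acc[l]["gy"].append(cy)
        acc[l]["gx"].append(cx)
        acc[l]["toff"].append((gxf - cx, gyf - cy))
        acc[l]["wh"].append((b.w, b.h))
        acc[l]["theta"].append(b.theta_deg)
        acc[l]["csl"].append(csl_mod.encode(b.theta_deg, csl_cfg))
        acc[l]["boxes"].append(b)
        return True

    for i, gts in enumerate(gts_per_image):
        for b in gts:
            if b.w > img_size or b.h > img_size:
                raise InvalidAnnotationError(
                    f"gt box {b.w:.1f}x{b.h:.1f} exceeds image size {img_size}")
            candidates = []          # (ratio, l, a, cy, cx, gxf, gyf)
            assigned = False
            for l, stride in enumerate(anchors.strides):
                H, W = grid_shapes[l]
                gxf, gyf = b.cx / stride, b.cy / stride
                cx0, cy0 = int(gxf), int(gyf)
                cx0, cy0 = min(cx0, W - 1), min(cy0, H - 1)
                cells = [(cy0, cx0)]
                fx, fy = gxf - cx0, gyf - cy0
                if fx < 0.5 and cx0 >= 1:
                    cells.append((cy0, cx0 - 1))
                elif fx >= 0.5 and cx0 < W - 1:
                    cells.append((cy0, cx0 + 1))
                if fy < 0.5 and cy0 >= 1:
                    cells.append((cy0 - 1, cx0))
                elif fy >= 0.5 and cy0 < H - 1:
                    cells.append((cy0 + 1, cx0))
                for a, (aw, ah) in enumerate(anchors.anchors[l]):
                    r = max(b.w / aw, aw / b.w, b.h / ah, ah / b.h)
                    for cy, cx in cells:
                        candidates.append((r, l, a, cy, cx, gxf, gyf))
                    if r < ratio_gate:
                        for cy, cx in cells:
                            assigned |= put(l, i, a, cy, cx, gxf, gyf, b)
            if not assigned:
                # crowded-scene fallback: best-ratio candidate with a free
                # slot, so every gt carries at least one training signal
                for r, l, a, cy, cx, gxf, gyf in sorted(candidates, key=lambda c: c[0]):
                    if put(l, i, a, cy, cx, gxf, gyf, b):
                        break

    out = []
    for l, stride in enumerate(anchors.strides):
        d = acc[l]
        out.append(LayerTargets(
            stride=stride, grid=tuple(grid_shapes[l]),
            img=np.asarray(d["img"], dtype=int), anchor=np.asarray(d["anchor"], dtype=int),
            gy=np.asarray(d["gy"], dtype=int), gx=np.asarray(d["gx"], dtype=int),
            toff=np.asarray(d["toff"], dtype=float).reshape(-1, 2),
            wh=np.asarray(d["wh"], dtype=float).reshape(-1, 2),
            theta=np.asarray(d["theta"], dtype=float),
            csl=np.asarray(d["csl"], dtype=float).reshape(-1, csl_cfg.K),
            boxes=d["boxes"],
        ))
    return out


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def decode(preds, anchors: AnchorSet, conf_threshold: float, csl_cfg: CSLConfig) -> list:
    """Convert raw grid predictions to per-image :class:`Detection` lists.

    Confidence is ``sigmoid(objectness) * sigmoid(class)``; positions above
    ``conf_threshold`` are turned into image-space oriented boxes with the
    angle decoded from the CSL logits.
    """
    if len(preds) != len(anchors.strides):
        raise ValueError(f"{len(preds)} prediction layers vs {len(anchors.strides)} anchor layers")
    n_img = preds[0].data.shape[0]
    out = [[] for _ in range(n_img)]
    for l, gp in enumerate(preds):
        if gp.stride != anchors.strides[l]:
            raise ValueError("prediction strides do not match anchor strides")
        p = gp.data.data if isinstance(gp.data, nn.Tensor) else np.asarray(gp.data)
        n, c, h, w = p.shape
        na, K = gp.na, gp.K
        p = p.reshape(n, na, 6 + K, h, w)
        conf = _sigmoid(p[:, :, 4]) * _sigmoid(p[:, :, 5])
        ii, aa, yy, xx = np.nonzero(conf > conf_threshold)
        for i, a, y, x in zip(ii, aa, yy, xx):
            v = p[i, a, :, y, x]
            cx = (2.0 * _sigmoid(v[0]) - 0.5 + x) * gp.stride
            cy = (2.0 * _sigmoid(v[1]) - 0.5 + y) * gp.stride
            aw, ah = anchors.anchors[l, a]
            bw = (2.0 * _sigmoid(v[2])) ** 2 * aw
            bh = (2.0 * _sigmoid(v[3])) ** 2 * ah
            theta = csl_mod.decode(v[6:], csl_cfg)
            box = OrientedBox.from_sides(cx, cy, bh, bw, theta)
            out[i].append(Detection(box=box, confidence=float(conf[i, a, y, x]),
                                    angle_scores=_sigmoid(v[6:])))
    return out
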