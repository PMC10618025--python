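"""Annotation and image I/O, tiling, oriented-box-aware augmentation,
dataset splitting, and channel-histogram diagnostics.

Coordinate convention: continuous image coordinates with pixel ``(r, c)``
covering the unit square ``[c, c+1) x [r, r+1)``, so a pixel center sits at
``(c + 0.5, r + 0.5)``.  Under this convention a horizontal flip of a
width-``W`` image maps ``x -> W - x`` and geometric box transforms commute
exactly with the corresponding array transforms.

Angles are stored internally in degrees (long-side convention of
:mod:`spikenet.rotgeom`); roLabelImg XML stores radians and is converted on
read.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .rotgeom import OrientedBox

__all__ = [
    "AnnotationRecord",
    "SplitManifest",
    "AnnotationError",
    "read_rolabelimg",
    "write_rolabelimg",
    "read_image",
    "write_image",
    "tile",
    "augment",
    "brightness_balance",
    "expand_dataset",
    "split",
    "channel_histograms",
    "letterbox",
]

STAGES = ("filling", "maturity", "unknown")
AUGMENT_OPS = ("identity", "hflip", "vflip", "rot90", "rot180", "rot270", "brightness")


class AnnotationError(ValueError):
    """Malformed annotation file or schema violation."""


@dataclass
class AnnotationRecord:
    """One annotated image: identifier, optional path, growth-stage tag,
    oriented boxes and (optionally) the pixel array itself (H, W, 3) uint8."""

    image_id: str
    boxes: list
    stage: str = "unknown"
    image_path: str | None = None
    image: np.ndarray | None = None
    source_id: str | None = None  # pre-augmentation identity (leakage guard)

    def __post_init__(self):
        if self.stage not in STAGES:
            raise AnnotationError(f"unknown stage tag {self.stage!r}; expected one of {STAGES}")
        if self.source_id is None:
            self.source_id = self.image_id

    def load_image(self) -> np.ndarray:
        if self.image is None:
            if self.image_path is None:
                raise AnnotationError(f"record {self.image_id} has neither pixels nor a path")
            self.image = read_image(self.image_path)
        return self.image


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_image(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


# ---------------------------------------------------------------------------
# roLabelImg XML
# ---------------------------------------------------------------------------


def _req(parent, tag, where):
    el = parent.find(tag)
    if el is None or el.text is None:
        raise AnnotationError(f"{where}: missing required field <{tag}>")
    return el.text.strip()


def read_rolabelimg(path) -> AnnotationRecord:
    """Parse a roLabelImg rotated-box XML file.

    Stored boxes are (cx, cy, w, h, angle) with the angle in radians and the
    stored ``w`` side lying along the stored angle; they are converted to the
    internal short/long + long-side-degree convention (sides swapped and the
    angle rotated by 90° when the stored height is the longer side).
    """
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:  # carries (line, column)
        raise AnnotationError(f"{path}: malformed XML at line {exc.position[0]}: {exc.msg}") from exc
    boxes = []
    for i, obj in enumerate(root.iterfind("object")):
        where = f"{path} object[{i}]"
        name = _req(obj, "name", where)
        rb = obj.find("robndbox")
        if rb is None:
            raise AnnotationError(f"{where}: missing required field <robndbox>")
        cx = float(_req(rb, "cx", where))
        cy = float(_req(rb, "cy", where))
        w = float(_req(rb, "w", where))
        h = float(_req(rb, "h", where))
        ang = math.degrees(float(_req(rb, "angle", where)))
        boxes.append(OrientedBox.from_sides(cx, cy, w, h, ang, name))
    stage_el = root.find("stage")
    stage = stage_el.text.strip() if stage_el is not None and stage_el.text else "unknown"
    fn = root.find("filename")
    image_id = fn.text.strip() if fn is not None and fn.text else path.stem
    pth = root.find("path")
    return AnnotationRecord(
        image_id=image_id,
        boxes=boxes,
        stage=stage,
        image_path=pth.text.strip() if pth is not None and pth.text else None,
    )


def write_rolabelimg(rec: AnnotationRecord, path, image_size=None) -> None:
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = rec.image_id
    if rec.image_path:
        ET.SubElement(root, "path").text = str(rec.image_path)
    ET.SubElement(root, "stage").text = rec.stage
    if image_size is None and rec.image is not None:
        image_size = (rec.image.shape[1], rec.image.shape[0])
    if image_size is not None:
        sz = ET.SubElement(root, "size")
        ET.SubElement(sz, "width").text = str(image_size[0])
        ET.SubElement(sz, "height").text = str(image_size[1])
        ET.SubElement(sz, "depth").text = "3"
    for b in rec.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = b.cls
        ET.SubElement(obj, "type").text = "robndbox"
        rb = ET.SubElement(obj, "robndbox")
        ET.SubElement(rb, "cx").text = f"{b.cx:.6f}"
        ET.SubElement(rb, "cy").text = f"{b.cy:.6f}"
        # canonical storage: w along the stored angle = long side
        ET.SubElement(rb, "w").text = f"{b.h:.6f}"
        ET.SubElement(rb, "h").text = f"{b.w:.6f}"
        ET.SubElement(rb, "angle").text = f"{math.radians(b.theta_deg):.8f}"
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode")


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------


def tile(image: np.ndarray, boxes, tile_size: int = 150):
    """Center-crop to 2*tile_size square, cut into a 2x2 grid of tiles, and
    reassign each box to the tile containing its center (half-open tile
    intervals ``[x0, x0 + tile_size)``).

    Returns ``(tiles, dropped)`` where ``tiles`` is a list of four
    ``(tile_image, tile_boxes)`` pairs in row-major order and ``dropped``
    counts boxes whose centers fell outside the cropped region.
    """
    H, W = image.shape[:2]
    side = 2 * tile_size
    if H < side or W < side:
        raise ValueError(f"image {W}x{H} smaller than required {side}x{side}")
    off_y, off_x = (H - side) // 2, (W - side) // 2
    crop = image[off_y:off_y + side, off_x:off_x + side]
    tiles = [
        [crop[r * tile_size:(r + 1) * tile_size, c * tile_size:(c + 1) * tile_size], []]
        for r in range(2) for c in range(2)
    ]
    dropped = 0
    for b in boxes:
        x, y = b.cx - off_x, b.cy - off_y
        if not (0 <= x < side and 0 <= y < side):
            dropped += 1
            continue
        r, c = int(y // tile_size), int(x // tile_size)
        tiles[2 * r + c][1].append(
            OrientedBox(x - c * tile_size, y - r * tile_size, b.w, b.h, b.theta_deg, b.cls)
        )
    return [(img, bx) for img, bx in tiles], dropped


def tile_record(rec: AnnotationRecord, tile_size: int = 150):
    """Tile an :class:`AnnotationRecord` into four records (row-major)."""
    tiles, dropped = tile(rec.load_image(), rec.boxes, tile_size)
    out = []
    for k, (img, bx) in enumerate(tiles):
        out.append(AnnotationRecord(
            image_id=f"{rec.image_id}__t{k}", boxes=bx, stage=rec.stage, image=img,
        ))
    return out, dropped


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def _flip_theta(t):
    return (180.0 - t) % 180.0


def augment(rec: AnnotationRecord, op: str, scale: float = 1.0) -> AnnotationRecord:
    """Apply one augmentation with consistent pixel and box transforms.

    ``op`` is one of ``identity, hflip, vflip, rot90, rot180, rot270,
    brightness``; rotations require square tiles; ``brightness`` scales all
    bands by ``scale`` (clamped to 8-bit range) and leaves boxes unchanged.
    Rotation angles follow image coordinates (y down): rot90 maps
    ``(x, y) -> (S - y, x)`` and adds 90° to the box angle.
    """
    img = rec.load_image()
    H, W = img.shape[:2]
    if op in ("rot90", "rot270") and H != W:
        raise ValueError(f"{op} requires a square tile, got {W}x{H}")
    bxs = rec.boxes
    if op == "identity":
        out_img, out_boxes = img.copy(), list(bxs)
    elif op == "hflip":
        out_img = img[:, ::-1].copy()
        out_boxes = [OrientedBox(W - b.cx, b.cy, b.w, b.h, _flip_theta(b.theta_deg), b.cls) for b in bxs]
    elif op == "vflip":
        out_img = img[::-1].copy()
        out_boxes = [OrientedBox(b.cx, H - b.cy, b.w, b.h, _flip_theta(b.theta_deg), b.cls) for b in bxs]
    elif op == "rot90":
        out_img = np.rot90(img, k=-1).copy()
        out_boxes = [OrientedBox(W - b.cy, b.cx, b.w, b.h, b.theta_deg + 90.0, b.cls) for b in bxs]
    elif op == "rot180":
        out_img = img[::-1, ::-1].copy()
        out_boxes = [OrientedBox(W - b.cx, H - b.cy, b.w, b.h, b.theta_deg, b.cls) for b in bxs]
    elif op == "rot270":
        out_img = np.rot90(img, k=1).copy()
        out_boxes = [OrientedBox(b.cy, H - b.cx, b.w, b.h, b.theta_deg + 90.0, b.cls) for b in bxs]
    elif op == "brightness":
        out_img = np.clip(img.astype(np.float64) * scale, 0, 255).astype(np.uint8)
        out_boxes = list(bxs)
    else:
        raise ValueError(f"unknown augmentation op {op!r}; expected one of {AUGMENT_OPS}")
    return AnnotationRecord(
        image_id=f"{rec.image_id}__{op}", boxes=out_boxes, stage=rec.stage,
        image=out_img, source_id=rec.source_id,
    )


def brightness_balance(image: np.ndarray, target_mean: float = 128.0) -> np.ndarray:
    """Gray-world illumination normalization: scale the image so its mean
    luminance equals ``target_mean`` (clamped to 8-bit range)."""
    m = float(image.mean())
    if m <= 0:
        return image.copy()
    return np.clip(image.astype(np.float64) * (target_mean / m), 0, 255).astype(np.uint8)


_DIHEDRAL = [
    ("identity", False), ("rot90", False), ("rot180", False), ("rot270", False),
    ("identity", True), ("rot90", True), ("rot180", True), ("rot270", True),
]


def expand_dataset(records, balance_target: float = 128.0):
    """8x augmentation: the dihedral-4 set {identity, rot90, rot180, rot270}
    x {no-flip, hflip}, each followed by brightness balance.  All eight
    variants keep the source record's ``source_id`` so splits can keep them
    together."""
    out = []
    for rec in records:
        for k, (rot, flip) in enumerate(_DIHEDRAL):
            r = augment(rec, rot)
            if flip:
                r = augment(r, "hflip")
            img = brightness_balance(r.image, balance_target)
            out.append(AnnotationRecord(
                image_id=f"{rec.image_id}__aug{k}", boxes=r.boxes, stage=rec.stage,
                image=img, source_id=rec.source_id,
            ))
    return out


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


@dataclass
class SplitManifest:
    seed: int
    train: list
    val: list
    test: list

    def partition_of(self) -> dict:
        d = {}
        for part in ("train", "val", "test"):
            for i in getattr(self, part):
                d[i] = part
        return d

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# seed={self.seed}\n")
            for i, part in self.partition_of().items():
                fh.write(f"{i}\t{part}\n")

    @classmethod
    def load(cls, path) -> "SplitManifest":
        seed, parts = 0, {"train": [], "val": [], "test": []}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("# seed="):
                    seed = int(line.split("=", 1)[1])
                    continue
                if not line or line.startswith("#"):
                    continue
                ident, part = line.split("\t")
                parts[part].append(ident)
        return cls(seed, parts["train"], parts["val"], parts["test"])


def split(records, seed: int, ratios=(0.7, 0.2, 0.1)) -> SplitManifest:
    """Seeded 7:2:1 split keeping all augmented variants of one source tile
    in the same partition (leakage guard).  Partition sizes match the ratios
    within one item."""
    if len(records) < 10:
        raise ValueError(f"need at least 10 records to split, got {len(records)}")
    groups: dict[str, list[str]] = {}
    for r in records:
        groups.setdefault(r.source_id, []).append(r.image_id)
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    n = len(records)
    targets = [r * n for r in ratios]
    parts: list[list[str]] = [[], [], []]
    counts = [0.0, 0.0, 0.0]
    for k in keys:
        ids = groups[k]
        # whole group to the partition with the largest relative deficit
        j = int(np.argmax([(t - c) / t for t, c in zip(targets, counts)]))
        parts[j].extend(ids)
        counts[j] += len(ids)
    return SplitManifest(seed=seed, train=parts[0], val=parts[1], test=parts[2])


# ---------------------------------------------------------------------------
# Diagnostics and letterboxing
# ---------------------------------------------------------------------------


def channel_histograms(images) -> np.ndarray:
    """Exact per-band 256-bin pixel-value counts, summed over images.

    Returns a (3, 256) integer array (R, G, B)."""
    hist = np.zeros((3, 256), dtype=np.int64)
    for img in images:
        for c in range(3):
            hist[c] += np.bincount(img[..., c].ravel(), minlength=256)
    return hist


def letterbox(image: np.ndarray, boxes, size: int = 160, fill: int = 114):
    """Pad an image to ``size`` x ``size`` with gray borders (no rescaling)
    and shift box coordinates accordingly.  Returns
    ``(padded_image, shifted_boxes, (pad_x, pad_y))``."""
    H, W = image.shape[:2]
    if H > size or W > size:
        raise ValueError(f"image {W}x{H} larger than letterbox size {size}")
    pad_y, pad_x = (size - H) // 2, (size - W) // 2
    out = np.full((size, size, image.shape[2]), fill, dtype=image.dtype)
    out[pad_y:pad_y + H, pad_x:pad_x + W] = image
    shifted = [OrientedBox(b.cx + pad_x, b.cy + pad_y, b.w, b.h, b.theta_deg, b.cls) for b in boxes]
    return out, shifted, (pad_x, pad_y)
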