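"""Synthetic two-stage wheat-canopy scene generator.

Emulates the color structure of UAV wheat imagery at two growth stages:
*filling* (green-dominant background, green-yellow spikes) and *maturity*
(yellow/red-dominant background, golden spikes), with many small, dense,
arbitrarily oriented spikes (~12–36 px long side in a 150x150 px tile).
Spikes are rendered as anti-aliased filled ellipses with short awn streaks
at the tips; the ground truth for each spike is the ellipse's tight rotated
rectangle.  The stage-shifted R/G/B channel statistics are the distribution
shift the color-transform network is designed to bridge.

It does not attempt photorealism: no 3-D canopy structure, shadows, wind
blur or soil texture beyond low-frequency color noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .dataio import AnnotationRecord, SplitManifest, split
from .rotgeom import OrientedBox, rotated_iou

__all__ = ["SceneConfig", "STAGE_PALETTES", "generate_scene", "generate_dataset"]

# per-stage (background mean RGB, spike mean RGB); sigma below applies to both
STAGE_PALETTES = {
    "filling": {"background": (70.0, 110.0, 55.0), "spike": (150.0, 160.0, 90.0)},
    "maturity": {"background": (150.0, 130.0, 70.0), "spike": (195.0, 170.0, 110.0)},
}


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic canopy tile."""

    size: int = 150
    stage: str = "filling"
    count_mean: float = 25.0          # Poisson mean number of spikes
    long_range: tuple = (12.0, 36.0)  # spike long side, px
    aspect_range: tuple = (2.5, 5.0)  # long/short side ratio
    palette_sigma: float = 12.0       # per-spike / low-frequency color jitter
    noise_sigma: float = 6.0          # per-pixel sensor noise
    occlusion_cap: float = 0.3        # max pairwise rotated IoU between spikes
    max_tries: int = 40               # placement retries per spike
    seed: int = 0

    def __post_init__(self):
        if self.stage not in STAGE_PALETTES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.count_mean < 0:
            raise ValueError("count_mean must be >= 0")
        if self.long_range[1] >= self.size:
            raise ValueError("spike long side must fit inside the tile")


def _render_ellipse(img: np.ndarray, box: OrientedBox, color: np.ndarray) -> None:
    """Alpha-composite an anti-aliased filled ellipse inscribed in ``box``."""
    S = img.shape[0]
    t = math.radians(box.theta_deg)
    ct, st = math.cos(t), math.sin(t)
    a, b = box.h / 2.0, box.w / 2.0  # semi-long, semi-short
    reach = a + 1.0
    x0, x1 = max(0, int(box.cx - reach)), min(S, int(box.cx + reach) + 1)
    y0, y1 = max(0, int(box.cy - reach)), min(S, int(box.cy + reach) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx = (xs + 0.5) - box.cx
    dy = (ys + 0.5) - box.cy
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    r = np.sqrt(u**2 + v**2)
    # ~1 px anti-aliased edge: alpha = 0.5 at r = 1
    edge = 2.0 / (a + b)
    alpha = np.clip(0.5 + (1.0 - r) / (2.0 * edge), 0.0, 1.0)
    region = img[y0:y1, x0:x1]
    region += alpha[..., None] * (color[None, None, :] - region)


def _render_awns(img: np.ndarray, box: OrientedBox, color: np.ndarray,
                 rng: np.random.Generator) -> None:
    """Thin bright streaks extending from the spike tips along the long axis."""
    S = img.shape[0]
    t = math.radians(box.theta_deg)
    for tip in (-1.0, 1.0):
        for _ in range(2):
            jitter = math.radians(rng.normal(0.0, 8.0))
            ux, uy = math.cos(t + jitter), math.sin(t + jitter)
            length = box.h * rng.uniform(0.12, 0.25)
            n = max(2, int(length * 2))
            s = np.linspace(0.0, length, n)
            xs = box.cx + tip * ux * (box.h / 2.0 + s)
            ys = box.cy + tip * uy * (box.h / 2.0 + s)
            ix, iy = xs.astype(int), ys.astype(int)
            keep = (ix >= 0) & (ix < S) & (iy >= 0) & (iy < S)
            img[iy[keep], ix[keep]] += 0.5 * (color - img[iy[keep], ix[keep]])


def generate_scene(cfg: SceneConfig):
    """Render one tile; returns ``(image_uint8, AnnotationRecord)``.

    Deterministic given ``cfg.seed``.  If a spike cannot be placed under the
    occlusion cap within ``max_tries`` attempts it is skipped; the number of
    skipped spikes is stored on the record as ``rec.n_placement_failures``.
    """
    rng = np.random.default_rng(cfg.seed)
    S = cfg.size
    pal = STAGE_PALETTES[cfg.stage]
    bg = np.asarray(pal["background"], dtype=float)
    sp = np.asarray(pal["spike"], dtype=float)

    # background: low-frequency color blotches + per-pixel sensor noise
    img = np.empty((S, S, 3), dtype=float)
    for c in range(3):
        blotch = gaussian_filter(rng.normal(0.0, 1.0, (S, S)), sigma=8.0)
        blotch *= cfg.palette_sigma / max(blotch.std(), 1e-9)
        img[..., c] = bg[c] + blotch

    n_target = int(rng.poisson(cfg.count_mean))
    boxes: list[OrientedBox] = []
    failures = 0
    for _ in range(n_target):
        placed = False
        for _try in range(cfg.max_tries):
            h = rng.uniform(*cfg.long_range)
            w = h / rng.uniform(*cfg.aspect_range)
            theta = rng.uniform(0.0, 180.0)
            margin = h / 2.0 + 1.0
            if 2 * margin >= S:
                continue
            cx = rng.uniform(margin, S - margin)
            cy = rng.uniform(margin, S - margin)
            cand = OrientedBox(cx, cy, w, h, theta)
            ok = True
            for b in boxes:
                if abs(b.cx - cx) + abs(b.cy - cy) > (b.h + h):
                    continue
                if rotated_iou(cand, b) > cfg.occlusion_cap:
                    ok = False
                    break
            if ok:
                boxes.append(cand)
                placed = True
                break
        if not placed:
            failures += 1

    for b in boxes:
        color = sp + rng.normal(0.0, cfg.palette_sigma, 3)
        _render_ellipse(img, b, color)
        _render_awns(img, b, color, rng)

    img += rng.normal(0.0, cfg.noise_sigma, img.shape)
    out = np.clip(img, 0, 255).astype(np.uint8)
    rec = AnnotationRecord(
        image_id=f"{cfg.stage}_{cfg.seed}", boxes=boxes, stage=cfg.stage, image=out,
    )
    rec.n_placement_failures = failures
    return out, rec


def generate_dataset(n_per_stage: int, seed: int = 0, split_seed: int | None = None,
                     **overrides):
    """Balanced two-stage dataset of ``2 * n_per_stage`` tiles.

    Per-image seeds are derived from the master ``seed``; any
    :class:`SceneConfig` field can be overridden by keyword.  Returns
    ``(records, SplitManifest)`` with the manifest produced by
    :func:`spikenet.dataio.split` (7:2:1).
    """
    if n_per_stage < 1:
        raise ValueError("n_per_stage must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_per_stage) % (2**31)
    records = []
    k = 0
    for stage in ("filling", "maturity"):
        for i in range(n_per_stage):
            cfg = SceneConfig(stage=stage, seed=int(child_seeds[k]), **overrides)
            _, rec = generate_scene(cfg)
            rec.image_id = f"{stage}_{i:04d}"
            rec.source_id = rec.image_id
            records.append(rec)
            k += 1
    manifest = split(records, seed if split_seed is None else split_seed)
    return records, manifest
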