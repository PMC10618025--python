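"""End-to-end model wrapper, training loop, inference and checkpointing.

The full model couples the optional color-transform front end with the
oriented detector; both train jointly by SGD (momentum 0.9, weight decay
1e-3, base learning rate 0.005, batch 16 by default, cosine decay) against
the multi-task loss.  Checkpoints are single ``.npz`` files holding every
parameter plus the resolved configuration, so a transform net and the
detector it was trained with always stay paired.
"""

from __future__ import annotations

import json
import math
import time
from pathlib import Path

import numpy as np

from . import detection_net as dnet
from . import nn
from .config import RunConfig
from .csl import CSLConfig
from .dataio import letterbox
from .detection_net import DetectionNet, default_anchors
from .losses import LossWeights, compute_loss
from .metrics import evaluate
from .rotgeom import OrientedBox, rotated_nms
from .transform_net import TransformNet

__all__ = ["SpikeNet", "train", "detect_images", "save_checkpoint", "load_checkpoint",
           "prepare_batch", "CHECKPOINT_VERSION"]

CHECKPOINT_VERSION = 1


class SpikeNet(nn.Module):
    """Color-transform front end (optional) + oriented detection network."""

    def __init__(self, cfg: RunConfig, rng: np.random.Generator = None):
        rng = rng or np.random.default_rng(cfg.train.seed)
        m = cfg.model
        self.cfg = cfg
        self.transform = None
        if m.transform_net:
            self.transform = TransformNet(
                channels=m.transform_channels, n_blocks=m.transform_blocks,
                n_codewords=m.n_codewords, rescale=m.transform_rescale, rng=rng)
        strides = dnet.ALL_STRIDES if m.micro_layer else dnet.ALL_STRIDES[1:]
        self.detector = DetectionNet(
            K=m.K, base_width=m.base_width, neck_width=m.neck_width,
            anchors=default_anchors(strides), micro_layer=m.micro_layer, rng=rng)

    @property
    def csl_cfg(self) -> CSLConfig:
        m = self.cfg.model
        return CSLConfig(K=m.K, beta=m.beta, sigma=m.sigma)

    @property
    def anchors(self):
        return self.detector.anchors

    def forward(self, img: nn.Tensor):
        """Returns (grid predictions, per-image alpha or None)."""
        alpha = None
        if self.transform is not None:
            img, alpha = self.transform(img)
        return self.detector(img), alpha

    __call__ = forward

    def transform_image(self, img: np.ndarray) -> np.ndarray:
        """Apply the learned color transform to one uint8 (H, W, 3) image;
        identity when the transform front end is disabled."""
        if self.transform is None:
            return img.copy()
        x = nn.Tensor(img.astype(np.float32).transpose(2, 0, 1)[None] / 255.0)
        alpha = self.transform.compute_alpha(x).data[0]
        from .transform_net import apply_color_transform

        return apply_color_transform(img, alpha, self.transform.rescale)


def prepare_batch(records, img_size: int):
    """Letterbox records to the network input size and normalize to [0, 1].

    Returns ``(tensor (N,3,S,S), boxes_per_image, (pad_x, pad_y))``.
    """
    imgs, boxes_pi = [], []
    pad = (0, 0)
    for rec in records:
        img, boxes, pad = letterbox(rec.load_image(), rec.boxes, size=img_size)
        imgs.append(img.astype(np.float32).transpose(2, 0, 1) / 255.0)
        boxes_pi.append(boxes)
    return nn.Tensor(np.stack(imgs)), boxes_pi, pad


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(model: SpikeNet, path, extra: dict = None) -> None:
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": model.cfg.to_dict(),
        "config_hash": model.cfg.hash(),
        "extra": extra or {},
    }
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path, expect_cfg: RunConfig = None) -> SpikeNet:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"checkpoint version {meta['version']} unsupported "
                             f"(expected {CHECKPOINT_VERSION})")
        cfg = RunConfig.from_dict(meta["config"])
        if expect_cfg is not None and expect_cfg.model != cfg.model:
            raise ValueError("checkpoint model configuration does not match the requested one")
        model = SpikeNet(cfg)
        model.load_state_dict({k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")})
    return model.eval()


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train(cfg: RunConfig, records, manifest=None, out_dir=None, max_steps: int = None,
          val_every_epoch: bool = True, log_fn=None):
    """Train a model on annotated records; fully seeded and reproducible.

    ``manifest`` (a :class:`~spikenet.dataio.SplitManifest`) selects train
    and validation subsets; without one, all records train and validation is
    skipped.  ``max_steps`` caps total optimizer steps (small-scale runs).
    Returns ``(model, log)`` where ``log`` is a list of dict records; if
    ``out_dir`` is given, writes ``train_log.jsonl``, ``best.npz`` (highest
    validation AP; falls back to the final model) and ``last.npz``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.train.seed)
    model = SpikeNet(cfg, rng=rng)
    if manifest is not None:
        by_id = {r.image_id: r for r in records}
        train_recs = [by_id[i] for i in manifest.train if i in by_id]
        val_recs = [by_id[i] for i in manifest.val if i in by_id]
    else:
        train_recs, val_recs = list(records), []
    if not train_recs:
        raise ValueError("no training records selected")

    det_params = model.detector.parameters()
    opt = nn.SGD(det_params, lr=cfg.train.lr, momentum=cfg.train.momentum,
                 weight_decay=cfg.train.weight_decay)
    t_lr = cfg.train.lr if cfg.train.transform_lr is None else cfg.train.transform_lr
    opt_t = None
    if model.transform is not None:
        opt_t = nn.SGD(model.transform.parameters(), lr=t_lr,
                       momentum=cfg.train.momentum,
                       weight_decay=cfg.train.weight_decay)
    bs = min(cfg.train.batch_size, len(train_recs))
    steps_per_epoch = max(1, len(train_recs) // bs)
    total_steps = cfg.train.epochs * steps_per_epoch
    if max_steps is not None:
        total_steps = min(total_steps, max_steps)
    m = cfg.model
    weights = LossWeights(
        localization=m.w_localization, objectness=m.w_objectness,
        classification=m.w_classification, angle=m.w_angle)
    csl_cfg = model.csl_cfg
    anchors = model.anchors

    model.train()
    log: list[dict] = []
    best_ap, best_state = -1.0, None
    step = 0
    epoch = 0
    t0 = time.time()
    while step < total_steps:
        epoch += 1
        order = rng.permutation(len(train_recs))
        for b0 in range(0, steps_per_epoch * bs, bs):
            if step >= total_steps:
                break
            batch = [train_recs[i] for i in order[b0:b0 + bs]]
            x, boxes_pi, _ = prepare_batch(batch, m.img_size)
            frac = 1.0
            if cfg.train.cosine_decay:
                frac = 0.5 * (1.0 + math.cos(math.pi * step / max(1, total_steps)))
            if step < cfg.train.warmup_steps:
                frac *= (step + 1) / cfg.train.warmup_steps
            opt.lr = cfg.train.lr * frac
            if opt_t is not None:
                opt_t.lr = t_lr * frac
            preds, alpha = model(x)
            grids = [(gp.data.shape[2], gp.data.shape[3]) for gp in preds]
            targets = dnet.encode_targets(boxes_pi, anchors, grids, m.img_size,
                                          csl_cfg, ratio_gate=m.anchor_ratio_gate)
            lb = compute_loss(preds, targets, anchors, csl_cfg, weights=weights,
                              use_ciou=m.use_ciou)
            opt.zero_grad()
            if opt_t is not None:
                opt_t.zero_grad()
            lb.total.backward()
            opt.step()
            if opt_t is not None:
                opt_t.step()
            step += 1
            rec = {"step": step, "epoch": epoch, "lr": round(opt.lr, 6),
                   "total": float(lb.total.data), "loc": lb.localization,
                   "obj": lb.objectness, "cls": lb.classification, "angle": lb.angle}
            if alpha is not None:
                rec["alpha"] = [round(float(v), 4) for v in alpha.data.mean(axis=0)]
            log.append(rec)
            if log_fn:
                log_fn(rec)
        if val_every_epoch and val_recs:
            ap = _validation_ap(model, val_recs)
            model.train()
            log.append({"step": step, "epoch": epoch, "val_ap": ap})
            if log_fn:
                log_fn(log[-1])
            if ap > best_ap:
                best_ap, best_state = ap, model.state_dict()
    log.append({"steps": step, "wall_time_s": round(time.time() - t0, 2),
                "resolved_config": cfg.to_dict()})

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, out_dir / "last.npz", extra={"steps": step})
        if best_state is not None:
            final = model.state_dict()
            model.load_state_dict(best_state)
            save_checkpoint(model, out_dir / "best.npz", extra={"val_ap": best_ap})
            model.load_state_dict(final)
        else:
            save_checkpoint(model, out_dir / "best.npz", extra={"steps": step})
        with open(out_dir / "train_log.jsonl", "w", encoding="utf-8") as fh:
            for rec in log:
                fh.write(json.dumps(rec) + "\n")
    return model, log


def _validation_ap(model: SpikeNet, recs) -> float:
    dets = detect_images(model, [r.load_image() for r in recs])
    return evaluate([[(d.box, d.confidence) for d in dd] for dd in dets],
                    [r.boxes for r in recs], model.cfg.eval.tp_iou).ap


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def detect_images(model: SpikeNet, images, conf_threshold: float = None,
                  nms_iou: float = None, batch_size: int = 8,
                  max_pre_nms: int = 300):
    """Run the full inference pipeline on raw images.

    letterbox -> color transform (if enabled) -> forward -> decode ->
    rotated NMS -> map coordinates back to the original frame.  Returns one
    ``list[Detection]`` per input image.
    """
    model.eval()
    ecfg = model.cfg.eval
    conf = ecfg.conf_threshold if conf_threshold is None else conf_threshold
    nms_thr = ecfg.nms_iou if nms_iou is None else nms_iou
    m = model.cfg.model
    out = []
    for b0 in range(0, len(images), batch_size):
        chunk = images[b0:b0 + batch_size]
        imgs, pads = [], []
        for img in chunk:
            padded, _, pad = letterbox(img, [], size=m.img_size)
            imgs.append(padded.astype(np.float32).transpose(2, 0, 1) / 255.0)
            pads.append(pad)
        x = nn.Tensor(np.stack(imgs))
        preds, _ = model(x)
        decoded = dnet.decode(preds, model.anchors, conf, model.csl_cfg)
        for dd, (px, py), img in zip(decoded, pads, chunk):
            dd = sorted(dd, key=lambda d: -d.confidence)[:max_pre_nms]
            pairs = rotated_nms([(d.box, d.confidence) for d in dd], nms_thr)
            h, w = img.shape[:2]
            kept = []
            for box, c in pairs:
                cx, cy = box.cx - px, box.cy - py
                if not (0 <= cx <= w and 0 <= cy <= h):
                    continue
                kept.append(dnet.Detection(
                    box=OrientedBox(cx, cy, box.w, box.h, box.theta_deg, box.cls),
                    confidence=c))
            out.append(kept)
    return out
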