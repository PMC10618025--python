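# spikenet

Oriented detection of wheat spikes in UAV canopy imagery, across growth
stages.

Wheat spikes in nadir drone images are small (tens of pixels), dense,
elongated and arbitrarily oriented — and their color changes drastically
between the grain-filling stage (green canopy, green-yellow spikes) and
maturity (golden canopy, red-shifted spikes), so a detector trained on one
stage collapses on the other. `spikenet` implements a one-stage oriented
detector addressing both problems:

- **Oriented boxes** `(x, y, w, h, cls, θ)` with `w ≤ h` and the long-side
  angle `θ ∈ [0°, 180°)`; exact rotated IoU, rotated NMS, and the CIoU
  localization loss
  `L_CIoU = 1 − IoU + l²(O_A, O_B)/d² + γ` (center distance normalized by
  the enclosing-box diagonal, plus an aspect-consistency term).
- **Circular Smooth Label (CSL)** angle classification: `θ` is classified
  over `K` bins against a circularly wrapped Gaussian window
  `CSL(x) = g(x)` for `|x − θ| < β` (else 0), so near-miss angles are only
  mildly penalized and the 179°/1° wrap is handled correctly.
- **Micro-scale detection head** at 1/4 input resolution (stride 4), added
  to the usual 8/16/32 pyramid specifically for spikes under ~16 px.
- **Color-transform front end**: residual blocks + a channel-attention
  domain adapter (AFAM), then bag-of-visual-words pooling + a softmax head
  (TPGM) emitting per-band factors `α` with `Σα = 1`; the detector sees
  `I′ = α·I` (rescaled), trained jointly so color differences between
  stages can be reduced before detection.
- The **evaluation suite** used for this task: precision, recall,
  all-point AP at rotated IoU 0.5, circular angle errors (RMSE_z, MAE_z)
  and counting errors (RMSE_c, rRMSE_c, MAE_c).
- A **synthetic two-stage canopy generator** so the whole method trains
  and evaluates on a desk CPU in minutes, with the stage color shift the
  transform network is meant to bridge.

The networks run on a small NumPy autodiff engine included in the package
(`spikenet.nn`): im2col convolutions, batch norm, SGD with momentum —
every gradient finite-difference-checked in the tests.

## Worked example

```sh
# 1. generate a 2-stage synthetic dataset (60 filling + 60 maturity tiles)
spikenet generate --out data --n-per-stage 60 --seed 1

# 2. train (YAML config optional; defaults follow the reference recipe)
spikenet train --data data --out run --epochs 20

# 3. detect on the test images and draw overlays
spikenet detect --checkpoint run/best.npz --images data/images --out dets --overlay

# 4. score against the ground truth
spikenet evaluate --detections dets --ground-truth data/labels --out report.json
```

A short library session (what the acceptance script does, in miniature):

```python
import numpy as np
from spikenet import RunConfig, evaluate, detect_images, train
from spikenet.synthfield import SceneConfig, generate_scene

recs = [generate_scene(SceneConfig(stage=s, seed=i))[1]
        for i in range(30) for s in ("filling", "maturity")]
cfg = RunConfig.from_dict({
    "model": {"w_localization": 0.3, "w_objectness": 2.0, "w_angle": 2.0},
    "train": {"batch_size": 8, "lr": 4.0, "epochs": 10000}})
model, log = train(cfg, recs, max_steps=250, val_every_epoch=False)

test = [generate_scene(SceneConfig(stage=s, seed=1000 + i))[1]
        for i in range(8) for s in ("filling", "maturity")]
dets = detect_images(model, [r.image for r in test])
print(evaluate([[(d.box, d.confidence) for d in dd] for dd in dets],
               [r.boxes for r in test], 0.5).report())
```

On one CPU this trains in a few minutes. `scripts/acceptance.py --seed 1`
(same pipeline, 100 training scenes, 250 SGD steps, 24 held-out scenes)
prints

```
"test_ap":         0.6389
"test_precision":  0.5426
"test_recall":     0.717
"angle_rmse_deg":  6.476
"angle_mae_deg":   5.125
"count_rmse":      8.663
"count_rrmse":     0.4246
"count_mae":       7.958
"train_loss_drop_pct": 72.42
```

i.e. after a minutes-scale schedule the detector reaches ~64% average
precision at rotated IoU 0.5 on held-out synthetic scenes, recovers spike
orientations to ~6.5° RMSE, and counts the ~25 spikes per tile with ~8.7
RMSE; longer schedules improve all of these (the overfit check in the test
suite reaches AP ≥ 0.9 on its training tiles in 200 steps).

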