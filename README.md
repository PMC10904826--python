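# attnguide

Attention-guided lesion classification for panoramic-radiograph-style
images with **partial location labels**. A CNN classifier's class-activation
attention (Grad-CAM) is supervised on a configurable fraction of
location-labelled samples through a differentiable soft-mask IoU loss, so
that even a small number of lesion outlines steers the network's focus —
improving both localization and fine-grained classification.

The package contains:

- **`attnguide.synthetic`** — a phantom radiograph generator (two smooth
  "jaw" bands, free-form lesion blobs with exact ground-truth masks,
  three classes: `Normal`, `CystTumor`, `LMBD` posterior mimic) so the
  whole pipeline is testable without clinical data.
- **`attnguide.augment`** — intensity jitter (brightness ±5%, contrast
  ±10%), joint horizontal flip (p = 0.5), the **trapezoid projective
  transform** (base width ±5%, applied jointly to image and mask), and
  the center border-crop (1280×720 → 940×520 by default).
- **`attnguide.attention`** — the math core: Grad-CAM map extraction,
  soft mask `s(ω(H̄ − θ))` with ε-guarded min-max normalisation,
  differentiable soft IoU, the conditional attention loss
  `1 − IoU(H̃, Y)` (0 for unlabelled samples), softmax cross-entropy and
  the weighted total objective `α_cls·L_cls + α_att·L_att`.
- **`attnguide.model`** — CNN → GAP → dropout → linear-head classifiers
  with closed-form CAM access (NumPy-only; includes a minimal autodiff
  engine in `attnguide.autodiff`, so no deep-learning framework is
  required).
- **`attnguide.training`** — stratified 6:2:2 splits, exact-count
  attention-label budgets, SGD/Adam with cosine annealing, early
  stopping, repeated runs, and the augmentation ablation grid.
- **`attnguide.evaluation`** — macro-averaged one-vs-rest
  accuracy/sensitivity/specificity, attention-map localization IoU, and
  heat-overlay export.

## Command line

```bash
# generate a phantom dataset with masks and a CSV manifest
attnguide generate --out data/ --per-class 20 --attention-rate 1.0 --seed 0 \
    --width 320 --height 180

# train one model (YAML config mirrors TrainConfig/LossConfig/AugmentationConfig)
attnguide train --manifest data/manifest.csv --config cfg.yaml \
    --attention-rate 0.05 --seed 0 --out runs/r005

# the attention-rate sweep (mean ± sd over repeats, per rate)
attnguide experiment --manifest data/manifest.csv --rates 0,0.05,0.1,0.2,0.5,1.0 \
    --repeats 5 --seed 0 --out runs/sweep

# augmentation ablation grid
attnguide ablate --manifest data/manifest.csv --repeats 5 --seed 0 --out runs/abl
```

Example config:

```yaml
backbone: small
optimizer: adam-decoupled   # default is plain sgd
epochs: 20
cosine_T_max: 20
patience: 20
batch_size: 8
loss:
  omega: 15.0
  gradcam_relu: false
augmentation:
  crop_size: [236, 130]
```

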