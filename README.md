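# busseg

Breast-ultrasound lesion segmentation with a residual/dilated/attention-gate
encoder-decoder network, implemented in pure numpy (including training via a
small built-in reverse-mode autodiff engine) so it runs anywhere scientific
Python runs — no deep-learning framework required.

## What's inside

- `busseg.blocks` — the computational building blocks as pure,
  shape-contracted functions: residual units (`conv(S)-BN-ReLU-conv-BN` plus
  a projected shortcut), dilated convolutions with their receptive-field
  accounting (`(K+1)(r-1)+K`), the six-branch dilated bridge
  (r = 1, 2, 4, 8, 16, 32, summed and upsampled x2) and the one-channel
  attention gate.
- `busseg.models` — deterministic model assembly from a `ModelConfig`:
  a 6-unit encoder (stride 1, then five stride-2 halvings), the dilated
  bridge, 5 decoder stages with attention-gated skips, and a 1x1 + sigmoid
  head.  Four named variants: `rdau` (all three components), `rau` (no
  dilated bridge), `dau` (no residual shortcuts), `rdu` (no attention
  gates).
- `busseg.metrics` — the nine-score battery (Loss, Acc, DC, Sen, Sp, F1,
  Pc, M-IOU, ROC-AUC, plus PR-AUC), Dice coefficient/loss with smoothing,
  pooled pixel confusion counts, mean lesion IOU.
- `busseg.augment` — paired affine expansion: vertical/horizontal shift,
  shear and horizontal flip applied identically to image and mask
  (4 transformed copies per original).
- `busseg.phantom` — seeded synthetic B-mode phantoms: hypoechoic lesions
  (smooth elliptical = benign-like, spiculated = malignant-like) under
  mean-one multi-look speckle, with exact ground-truth masks.
- `busseg.pipeline` — train / evaluate / predict plus resolution
  (64/96/128/256) and ablation sweeps, all seeded and reproducible from the
  frozen per-run config.
- `busseg.nn` — the minimal NHWC autodiff engine (SAME-padded
  strided/dilated conv, batch norm, nearest upsample, concat, soft Dice
  loss, Adam).

## CLI

```sh
# 200 synthetic phantoms with masks and a manifest
busseg generate --n 200 --side 64 --seed 0 --out data/

# train (YAML config and/or flags); writes weights, history, frozen config
busseg train --variant rdau --input-side 64 --epochs 10 \
             --learning-rate 3e-4 --seed 1 --out-dir runs/demo

# evaluate saved weights: nine-score row, per-image CSV, ROC/PR curves
busseg evaluate --config runs/demo/run_config.yaml \
                --weights runs/demo/weights.npz --out-dir runs/demo/eval

# predictions + contour overlays for a directory of images
busseg predict --config runs/demo/run_config.yaml \
               --weights runs/demo/weights.npz --images data/ --out-dir preds/

# the two experiment protocols
busseg sweep-resolution --config cfg.yaml
busseg sweep-ablation --config cfg.yaml
```

With no `--data-dir`, training uses the seeded synthetic benchmark
(`synthetic: {n_train, n_val, n_test, mix}` in the YAML config).  Directory
datasets follow the `<stem>.png` / `<stem>_mask.png` convention (PNG/BMP/
TIFF, lesion = 255).

## Notes

- Defaults mirror the reference protocol: batch size 32 up to 128x128
  inputs and 16 at 256x256, 300 epochs, Dice loss; the bundled benchmark
  configs scale this down to CPU scale.
- All randomness flows from explicit integer seeds; two runs with the same
  config are bit-identical.
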