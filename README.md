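# retinasr

Fundus image enhancement and five-grade diabetic-retinopathy classification,
exercisable end-to-end on synthetic graded fundus phantoms — no downloads,
no GPU. The package implements:

- **preprocessing** — ROI crop, grayscale, bilinear resize to 224×224,
  Gaussian smoothing with optional blending, per-image min-max
  normalization to [−1, 1];
- **super-resolution** — a hybrid local–global ×2 SR network whose core
  block combines a modulated 3×3 deformable convolution (adaptive local
  path), embedded-Gaussian non-local attention (inter-pixel global path),
  and a 2×2-patch transformer (patch-scope global path), with feature
  reuse across blocks and a pixel-shuffle + bicubic-residual
  reconstruction; plus a three-stage SRCNN baseline;
- **classification** — RefineNet-U, a U-Net encoder/bridge/decoder whose
  decoder output is flattened into a dropout/dense/softmax five-grade
  head, plus a plain CNN baseline;
- **evaluation** — confusion counts, per-class accuracy / precision /
  recall / F1 / specificity, MSE / PSNR / global-moment SSIM, one-vs-rest
  ROC AUC;
- **synthetic data** — seeded graded fundus phantoms (vessel trees,
  microaneurysms, hemorrhages, exudates, neovessel tufts) and LR/HR
  training pairs.

All networks run on a small numpy reverse-mode autodiff engine bundled
with the package (`retinasr._tensor`, `retinasr._layers`); there is no
deep-learning framework dependency, and training is deterministic under a
seed on a single CPU.

## CLI

Every subcommand takes `--config <yaml>`, `--seed <int>`, `--out`, and
`--log-level`, and logs its resolved configuration before running.

```sh
retinasr synth --n-per-grade 20 --side 448 --seed 1 --out data/
retinasr preprocess --in data/manifest.csv --out prep/
retinasr train-sr --model hlg --pairs prep/manifest.csv --seed 1 --out runs/sr/
retinasr enhance --model-ckpt runs/sr/sr_model --in prep/manifest.csv --out enhanced/
retinasr train-clf --model refinenet_u --manifest enhanced/manifest.csv --seed 1 --out runs/clf/
retinasr grade --model-ckpt runs/clf/clf_model --in enhanced/manifest.csv --out predictions.csv
retinasr evaluate --pred predictions.csv --truth enhanced/manifest.csv --out report.json
```

Configuration defaults (network depth/width, optimizer settings, phantom
parameters) live in `retinasr/config.py`; any YAML you pass is overlaid on
them.

## Layout

```
src/retinasr/
  _tensor.py, _layers.py   numpy autodiff engine + NN layers (internal)
  fundus_io.py             images, manifests, dataset splits
  preprocess.py            crop / resize / blur / blend / normalize
  sr_ops.py                deformable conv, non-local, patch transformer,
                           pixel shuffle (+ oracle-testable functional API)
  hlg_retinasr.py          SR network assembly, MSE training, checkpoints
  refinenet_u.py           U-Net classifier, baseline CNN, training
  metrics_eval.py          confusion/ROC/PSNR/SSIM machinery
  synthetic_fundus.py      phantom generator and LR/HR pair builder
  config.py, cli.py        YAML config and click CLI
```
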