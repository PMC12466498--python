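# chickendet

Occlusion-aware, low-light-robust detection of caged poultry (head–neck
targets, single class), built from three bespoke blocks on top of a
minimal anchor-free nano detection substrate:

* **MSEIExtractor** — a multi-scale edge information extractor: a
  {3, 6, 9, 12} adaptive-pooling pyramid (`MSEISelect`), high-frequency
  residual boosting (`EIEnhance`), and a dual-domain spatial/frequency
  selective attention (`DSM`) that is the exact identity at
  initialization, wrapped in a CSP-style stage block.
* **CGDown** — context-guided downsampling: stride-2 CBS that doubles
  channels, complementary depthwise-local and dilation-2 context
  branches, SiLU + 1×1 joint reduction, and squeeze-style global channel
  attention.
* **MultiSEAM / DHMSEAM** — occlusion attention from non-overlapping
  patch embeddings at kernels/strides 3, 5, 7, fused into a per-channel
  gate; `DHMSEAM` embeds it into both branches of the decoupled detect
  head with an unchanged raw output layout.

Everything runs on a small NumPy reverse-mode autograd engine
(`chickendet.nn`) — no GPU or deep-learning framework required — so the
models build, profile, train and evaluate on one CPU.

The package also ships the surrounding workflow: a four-stage image
enhancement pipeline used purely as an annotation aid (HSV directional
saturation → gamma → CLAHE → bilateral denoising) with filename-matched
label transfer, a procedural generator of caged-bird scenes (tiered
illumination, wire mesh, pipe/trough/crowding occluders) emitting YOLO
text labels, the 7:2:1 floor/remainder dataset split, two 100-image
special test sets, and a full detection metric stack (greedy IoU
matching, P/R/F1, 101-point mAP50/mAP50:95, radar-chart normalization
and polygon areas).

## Model variants and printed budgets

`chickendet.assembly.build_variant` assembles the baseline and every
ablation combination. Parameter counts are **fused** (batch norm folded
into the preceding conv, as model-summary tables print them); GFLOPs use
the multiply-accumulate-×2 convention on the fused graph at 640×640.

| variant        | head | extractor | downsample | params (M) | GFLOPs |
|----------------|:----:|:---------:|:----------:|-----------:|-------:|
| `baseline`     |      |           |            | 2.58       | 6.3    |
| `model1`       |  ✓   |           |            | 4.59       | 6.0    |
| `model2`       |      |     ✓     |            | 2.57       | 6.5    |
| `model3`       |      |           |     ✓      | 3.53       | 9.0    |
| `model6`       |      |     ✓     |     ✓      | 3.52       | 9.3    |
| `chicken-yolo` |  ✓   |     ✓     |     ✓      | 5.53       | 9.0    |

Replacement sites and block hyper-parameters are frozen constants in
`chickendet/assembly.py` (`MSEI_SITES`, `CGDOWN_SITES`,
`MSEAM_EXPANSION`), calibrated once against these budgets.

## CLI

```bash
chickendet build-summary --variant chicken-yolo --imgsz 640 --nc 1
chickendet synth --n 500 --out data/train --seed 7 --split
chickendet synth --n 100 --out data/special --special poor-light
chickendet enhance --in raw/ --out enhanced/ --params enhance.yaml
chickendet transfer-labels --labels enhanced-labels/ --originals raw/ --out dataset/
chickendet train --data data/train --variant chicken-yolo --seed 0 --width 0.0625
chickendet eval  --weights runs/train/best.npz --data data/test --json metrics.json
```

Model configs use a one-row-per-layer list dialect
(`[from, repeats, block, args]`, see `chickendet/scaffold/model.py`);
custom blocks register themselves in `BLOCK_REGISTRY` and are
addressable by name (`MSEIExtractor`, `CGDown`, `DHMSEAM`).

## Notes

* Training uses SGD (lr 0.01, momentum 0.937, weight decay 5e-4),
  early stopping with patience 50, and online translation/scaling/flip/
  Mosaic/Mixup augmentation; losses are CIoU + BCE + distribution-focal
  with a centre-inside-box static assigner.
* Enhanced images never enter train/val/test manifests;
  `chickendet.enhance.audit_manifest` enforces this.
* Minimum training image size for the full model is 224 px (the
  attention head needs a 7×7 stride-32 map and the pyramid a 12×12
  stride-16 map).
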