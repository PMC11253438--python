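# paddydetr

Detection of barnyard grass (*Echinochloa*) in UAV imagery of rice paddies,
as a set-prediction (DETR-style) problem with an encoder built for small
targets.  Barnyard grass is morphologically close to rice and, at typical
drone altitudes, a single plant covers only tens of pixels; the package is
aimed at researchers in agricultural remote sensing who want a transparent,
fully inspectable reference implementation of a multi-scale detection
pipeline — from LabelMe annotations and orthomosaic tiling through training
to COCO-style evaluation — that runs on a plain CPU.

Three classes are detected: the **field ridge** (raised earthen boundary),
the **single barnyard grass plant**, and the **continuous barnyard-grass
patch**.  Because no field imagery is distributed, a synthetic paddy-scene
generator reproduces the statistical structure the detector assumes (green
row-crop canvas, elongated ridge bands, small bright single plants between
the ridges, large dark patches), so every component is exercisable at desk
scale.

## Model

Given an image resized to 640×640×3, a four-stage residual backbone emits a
feature pyramid

* s3: 80×80×128 (stride 8), s4: 40×40×256 (stride 16), s5: 20×20×512 (stride 32),

which a **hybrid encoder** processes with branch-specific structure:

* **Transformer branch** on s5 → y1 (20×20×512), with **cascaded group
  attention (CGA)** in place of standard multi-head attention: head *j*
  reads only the *j*-th channel split X_ij of the input and the previous
  head's output,

      X̃_ij = Attn(X′_ij W_ij^Q, X′_ij W_ij^K, X′_ij W_ij^V),
      X′_ij = X_ij + X̃_i(j−1)  (j > 1),
      output = Concat_j[X̃_ij] W_i^P,

  so the Q/K/V projections cost exactly 1/h of standard MHA.
* **Dilated-CNN branch** on s3 → y2 (80×80×256): three parallel 3×3
  convolutions with dilations 6/12/18 (BN + ReLU, 1×1 residual per branch),
  concatenated 240 → fused 80 by a 1×1 convolution, then expanded to 256.
* **Cross-scale fusion** of (y1, s4, y2) → y3 (80×80×512), a top-down
  FPN-style pathway feeding a standard query-based decoder (100 queries,
  Hungarian matching, cross-entropy + L1 + GIoU losses).

Any stride-1 3×3 convolution can be swapped for a **partial convolution
(PConv)** that convolves only a contiguous slab of c_p = r·c channels and
passes the rest through unchanged: FLOPs are h·w·k²·c_p² — r² of a dense
convolution (1/16 at the typical r = 1/4) — and memory traffic
h·w·2c_p + k²·c_p² ≈ r of dense.

Everything, including convolutions, attention and backpropagation, is
implemented on numpy in `paddydetr.nn`; the only binary dependencies are
numpy/scipy/Pillow.

## Worked example

Train the quarter-width desk preset on 32 synthetic one-object scenes
(about five minutes on one CPU) and score it on its own training set:

```python
import numpy as np
from paddydetr.model import WeedDetector
from paddydetr.presets import sanity_scenes, sanity_model_config, sanity_train_config
from paddydetr.train import train_loop, image_to_input, detections_from
from paddydetr.evaluation import annotations_to_gts, evaluate
from paddydetr.nn import Tensor

scenes = sanity_scenes(32, seed=7)
model = WeedDetector(sanity_model_config(1))
history = train_loop(model, scenes, sanity_train_config(1))
loss = np.asarray(history["loss"])
print(f"loss: first-20 mean {loss[:20].mean():.2f} -> last-20 mean {loss[-20:].mean():.2f}")

model.eval()
gts = annotations_to_gts(scenes)
preds = [detections_from(model.predict(Tensor(image_to_input(s)[None]))[0],
                         s.width, s.height) for s in scenes]
summary = evaluate(preds, gts)
print(f"training-set mAP50 = {summary.map50:.3f}")
```

prints

```
loss: first-20 mean 14.15 -> last-20 mean 0.72
training-set mAP50 = 0.864
```

The loss falls by an order of magnitude as the queries learn to localise,
and the mean average precision at IoU 0.5 over the three classes shows the
pipeline detecting essentially every memorised object (class AP50s 0.977 /
0.695 / 0.921 for ridge / single plant / patch — the small single plants
are, as expected, the hardest).

The command line covers the same pipeline from a shell:

```
paddydetr synth-data --n 50 --seed 7 --out scenes/
paddydetr train --seed 1 --out runs/demo
paddydetr evaluate --gt scenes/annotations.json --pred preds.json --out runs/eval
paddydetr flops-report --config cfg.yaml --input-side 640 --out flops.csv
```

`flops-report` tabulates per-layer FLOPs and memory access; with PConv
enabled at r = 1/4 every replaced layer shows a flops ratio of 0.0625
against its dense counterpart.

## Layout

```
src/paddydetr/
  nn/          numpy autograd: tensors, conv/norm/linear layers, SGD & Adam
  data.py      annotation records, tiling, size strata, 4x augmentation, split
  synthetic.py paddy-scene generator
  io.py        LabelMe and COCO JSON
  pconv.py     partial convolution + cost model
  cga.py       cascaded group attention
  backbone.py  multi-scale pyramid
  encoder.py   transformer branch, dilated branch, cross-scale fusion
  head.py      decoder, Hungarian matching, losses
  model.py     assembled detector
  train.py     poly-decay schedule and training loop
  evaluation.py COCO-protocol metrics
  presets.py   desk-scale training preset
  config.py / cli.py   YAML experiment config and CLI
```
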