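# droughtvision

Tooling for detecting drought stress in chlorophyll-fluorescence (Fv/Fm)
imagery of plant seedlings. Fv/Fm — the maximum photochemical quantum
efficiency of photosystem II — declines early and monotonically under water
deficit, so an object detector over Fv/Fm maps can localize individual
plants/leaves and grade their drought severity before visible wilting. The
package targets a four-grade severity scale defined on soil relative
humidity W:

| severity | W interval | level |
|---|---|---|
| no drought | W ≥ 60% | 1 |
| mild | 50% ≤ W < 60% | 2 |
| moderate | 40% ≤ W < 50% | 3 |
| severe | 30% ≤ W < 40% | 4 |

## What's inside

* **CEAC (compound-eye apposition concatenation)** — `droughtvision.ceac`.
  Mosaic-batched inference in the style of an apposition compound eye: x²
  images are tiled into one canvas for a single detector pass, and
  detections are reverse-mapped into each tile's own normalized YOLO frame
  (`a = (a_abs − c_start)/W_tile`, …), with center-based tile assignment,
  half-open seam tie-breaks, clipping and a configurable retention fraction.
* **MSLA (multi-scale linear attention)** — `droughtvision.blocks.MSLA`.
  Channel split into four branches with residual depthwise convolutions at
  kernels 3/5/7/9, token-sequence linear attention per branch
  (`O = φ_q(Q)·(φ_k(K)ᵀ·V)` with row-softmax queries and column-softmax
  keys; never materializes an N×N matrix), learnable branch weights and a
  1×1 fusion convolution.
* **CMUNeXt block** — `droughtvision.blocks.CMUNeXtBlock`. Residual
  large-kernel depthwise stage plus pointwise expand/reduce, each stage
  followed by GELU and batch normalization.
* **Inner-CIoU loss** — `droughtvision.losses`. Auxiliary boxes scaled by a
  factor `ratio` about each box center; the regression loss is
  `L_CIoU + IoU − IoU_inner(ratio)` with a linear ratio schedule
  (default 1.25 → 0.75) over the training horizon.
* **MC-YOLOv13-L assembly** — `droughtvision.model`. A 34-layer detection
  graph (three scales, strides 8/16/32, 4 classes) described by a shipped
  architecture table (`configs/mc_yolov13_l.yaml`), built on the package's
  own numpy autograd engine (`droughtvision.nn`), with a desk-scale SGD
  trainer and prediction decoding.
* **Metrics** — `droughtvision.metrics`. Greedy confidence-ordered matching,
  precision/recall/F1, all-point-interpolated AP, mAP@50 and mAP@50-95.
* **Synthetic data** — `droughtvision.datagen`. A generator of Fv/Fm-style
  grayscale leaf scenes across the four grades, the augmentation suite
  (HSV jitter, mean/Gaussian/median blur, CutOut with 1–6 patches covering
  5–40% of the image, the 8-element D4 group, random brightness), and
  split-then-augment dataset construction with a leakage-checked lineage
  manifest.

## Worked example

```python
import numpy as np
from droughtvision.ceac import (DetectionRecord, compose_mosaic, denormalize,
                                split_detections)
from droughtvision.datagen import (GRADES, SceneSpec, generate_scene,
                                   grade_from_humidity)
from droughtvision.blocks import count_parameters
from droughtvision.metrics import MatchCounts, precision_recall_f1

g = grade_from_humidity(55.0)
print(f"W = 55% -> {g.severity} (level {g.level})")

spec = SceneSpec(side=640)
items = [generate_scene(spec, GRADES[i % 4], seed=i) for i in range(9)]
mosaic, labels, layout = compose_mosaic(items, x=3)
print(f"mosaic: {mosaic.shape}, tiles {layout.x}x{layout.x} of "
      f"{layout.W_tile}x{layout.H_tile}, {len(labels)} labels")

dets = [DetectionRecord(l.class_id, 0.9,
                        denormalize(l, layout.W_orig, layout.H_orig))
        for l in labels]
per_tile = split_detections(dets, layout)
print("recovered per tile:",
      [len(per_tile[(i, j)]) for i in range(3) for j in range(3)])

print("Conv[3,16,3,2] params:", count_parameters(("Conv", [3, 16, 3, 2])))
p, r, f1 = precision_recall_f1(MatchCounts(tp=93, fp=7, fn=5))
print(f"P={p:.4f} R={r:.4f} F1={f1:.4f}")
```

prints

```
W = 55% -> Mild Drought (level 2)
mosaic: (1920, 1920), tiles 3x3 of 640x640, 33 labels
recovered per tile: [3, 2, 4, 2, 6, 4, 6, 4, 2]
Conv[3,16,3,2] params: 464
P=0.9300 R=0.9490 F1=0.9394
```

Nine synthetic 640² Fv/Fm scenes are tiled into a 1920² mosaic whose 33
labels are carried into the mosaic frame; treating those labels as perfect
detections and splitting them back recovers every box in its original tile.
The conv-block count is the trainable-scalar total of a 3→16-channel 3×3
stride-2 convolution (no bias) plus batch normalization, and the last line
is the precision/recall/F1 arithmetic used throughout evaluation.

## Command line

```sh
droughtvision synth make --n 324 --variants 12 --seed 7 --out data/
droughtvision ceac compose --grid 3 --in data/images/val --out mosaic/
droughtvision ceac split --dets mosaic/preds.txt --layout mosaic/layout.yaml --out tiles/
droughtvision train --data data/ --epochs 2
droughtvision eval --gts labels/ --preds preds/ --iou 0.5
```

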