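# Methods

This note records the models, conventions and numerical choices behind
`droughtvision`, and what the synthetic-data experiments do and do not show.

## Coordinate conventions and CEAC geometry

All labels follow the YOLO text convention: `class cx cy w h`, box center
and size as fractions of the image, pixel origin at the top-left, x
rightward, y downward, coordinates treated as continuous (no half-pixel
offset). Denormalization multiplies by the canvas dimensions; tile
re-normalization subtracts the tile origin and divides by the tile size.

The compound-eye mosaic is an equal, gap-free tiling: `x` tiles per side,
`W_tile·x = W_orig`, tile (i, j) at `(j·W_tile, i·H_tile)`. Inputs that do
not match the tile size are bilinearly resized before pasting. Choices the
geometry itself does not dictate:

* **Straddling boxes** are assigned by box center, clipped to the assigned
  tile, and dropped when the clipped area retains less than 10% of the
  original (configurable `retention`). Center assignment matches YOLO label
  semantics.
* **Seam tie-break**: tiles are half-open intervals `[start, start+size)`,
  so a center exactly on a seam belongs to the right/bottom neighbour —
  deterministic and exhaustively tested along the seams.
* **Training-time use**: a mosaic step composes x² independently sampled
  training images (classes may mix). A grid of 3 (9 sub-images) is the
  default operating point.

With no seam-straddling boxes, compose→split is an exact identity (to 1e-9),
and detection counts are conserved; both are asserted over 1000 random
scenes.

## MSLA

Input (B, C, N, N) with C divisible by 4 is split into four channel blocks.
Branch i applies a residual depthwise convolution of kernel kᵢ ∈ {3,5,7,9}
(same padding) and ReLU, flattens to N² tokens of C/4 channels, and runs
linear attention: queries/keys/values are learned projections; φ_q is a
softmax over each query row, φ_k over each key column, and the product is
regrouped as `φ_q(Q)·(φ_k(K)ᵀ·V)` so cost is O(N·d²) and no N×N matrix
exists. Heads default to 1 per branch (head dim C/4) — the head count of the
original design is not published, so it is left configurable. Branch outputs
are scaled by learnable scalars w₁..w₄ (initialized to 1) and fused by a 1×1
convolution with bias (the bias makes the all-zero-fusion degenerate case
exact). Softmax numerics subtract the per-row/column maximum and add 1e-12
to denominators.

Equivalence to the explicit-attention order of operations is verified to
1e-5 against an oracle that materializes the N×N matrix, for N ≤ 32 and up
to 4 heads; every output row is verified to be a convex combination of the
aggregated key/value rows.

## CMUNeXt block

`f' = BN(GELU(dw_k(f) + f))`, `f'' = BN(GELU(pw_{C→E}(f')))`,
`f_out = BN(GELU(pw_{E→C}(f'')))`. The two channel-recombination stages are
full pointwise (1×1) convolutions — that is what the defining equations
state, even where prose descriptions call them depthwise. Defaults: kernel
7×7, expansion E = 4C, depth 1; the exact internal widths of the published
1,121,792-parameter stage are not recoverable from the printed table, so
these defaults follow the original CMUNeXt design and are configurable.

## Parameter accounting

Convolution blocks carry no convolution bias; batch normalization
contributes 2 trainable scalars per channel (running statistics are buffers,
not parameters). This convention uniquely reproduces all plain-Conv rows of
the reference architecture table (464, 2368, 9344, 8320, 36992, 147712) and
is verified arithmetically. It also pins:

* `DSConv` = depthwise conv + pointwise conv + a *single* BN after the
  pointwise stage (17,792 for [128,128,3,2]; 34,432 for [128,256,3,2]);
* `DownsampleConv(c)` = average pool + 1×1 conv c→2c + BN (33,280 at c=128);
* `FullPAD_Tunnel` = one learnable gate scalar: `a + gate·b`, gate
  initialized to 0.

Two totals are deliberately distinct. `total_parameters(graph)` sums the
reference per-layer column shipped with the architecture table (3,477,567).
`Model.count_parameters()` counts actual trainable scalars of the built
network (≈3.15 M): the interiors of C3k2_MSLA, A2C2f, HyperACE, the CMUNeXt
stage and the Detect head are not published, so this package supplies its
own designs honoring the channel/scale wiring of the table, and their
actual counts land near but not exactly on the reference column.

## Inner-CIoU loss

Auxiliary boxes share the source box center with both sides scaled by
`ratio`; their intersection width and height are each clamped at 0 before
multiplying (the raw formula is sign-unsafe for disjoint boxes). The
combined loss is `L_CIoU + IoU − IoU_inner(ratio)`; since
`L_CIoU + IoU = 1 + penalties`, this equals `(1 − IoU_inner)` plus the CIoU
penalties identically — both spellings are implemented and tested equal.
The CIoU aspect term uses the standard completion
`v = (4/π²)(arctan(w_gt/h_gt) − arctan(w/h))²`,
`α = v/((1−IoU)+v)` with α treated as a constant for gradients. At
ratio = 1 the loss reduces exactly to CIoU. Randomized sweeps confirm
non-negativity for ratio ≤ 1; negative corner cases for ratio > 1 would be
reported, not suppressed.

The ratio schedule is linear, default 1.25 → 0.75 over the training horizon:
enlarged auxiliary boxes early (wider regression basin under low overlap and
occlusion), shrunken boxes late (sharper localization sensitivity). The
original endpoints are not published; these bracket the identity
symmetrically and are configuration.

## Detection metrics

Matching is greedy one-to-one in descending confidence with ties broken by
detection id (ascending) for determinism; a detection is a true positive iff
its best-IoU unmatched same-class ground truth reaches the threshold.
Degenerate precision/recall (zero denominators) evaluate to 0 with a
warning. AP uses all-point interpolation,
`AP = Σ (r_{i+1} − r_i)·P_inter(r_{i+1})` with `P_inter(r)` the maximum
precision at recall ≥ r, verified against a 1e-4-step Riemann-sum oracle to
1e-3. mAP averages per-class AP; mAP@50-95 additionally averages over IoU
thresholds 0.50:0.05:0.95.

## Synthetic scenes and what they do (not) show

Scenes are 640² (configurable) grayscale canvases: a dim background with a
gentle illumination gradient, 2–6 axis-aligned elliptical leaf blobs with
mild radial falloff, additive Gaussian noise (σ = 0.015), and tight boxes.
Interior intensities are drawn around grade means 0.80/0.68/0.55/0.40 for
levels 1–4 (σ = 0.04) — plausible Fv/Fm physiology for a synthetic fixture,
strictly decreasing with severity by construction and validated. What real
Fv/Fm data has that these scenes do not: lobed/serrated leaf geometry and
petioles, spatially structured within-leaf stress patterns (vein-following
bands, edge-localized decline), occlusion between plants, pot and substrate
background, and sensor-specific noise. Passing tests therefore demonstrate
the correctness of the geometry, losses, metrics and training machinery —
not field-level detection accuracy.

Augmentation: HSV jitter operates on a green-to-red pseudo-color rendering
(single-channel maps have no hue) and converts back to luminance; blurs are
scipy.ndimage filters; CutOut paints 1–6 zero rectangles totalling 5–40% of
the image, with pixel-quantized sides nudged so the painted area always
lands inside that band and rejection-sampled placement to avoid overlap;
D4 applies one of the 8 symmetries of the square to image and labels
(area-preserving; inverses round-trip exactly). One augmentation kind is
sampled uniformly per variant, with parameters drawn per variant.

Dataset construction is split-then-augment: with 324 originals, 20%
validation hold-out (65), the 259 remaining split 8:2 (207/52), and 12
variants per original — the unique integer consistent with the published
2691/676/845 totals — each original contributes 13 images to its own split.
The lineage manifest is checked mechanically for cross-split leakage.
Humidity below 30% raises an out-of-scale error rather than clamping: the
severest defined grade starts at 30%, and silently clamping would fabricate
a grade.

## Numerical engine and desk-scale training

All network computation runs on a package-internal reverse-mode autograd
over float64 numpy arrays (`droughtvision.nn`): broadcast arithmetic,
batched matmul, grouped/depthwise 2-D convolution via strided windows and
einsum, reductions, batch norm, nearest upsampling and average pooling.
Gradients are verified against central differences.

The trainer is intentionally desk-scale: direct box regression
(sigmoid-offset centers, exponential sizes per scale) with Inner-CIoU,
plus binary cross-entropy classification over all cells, using the loss
gains box 7.5 / cls 0.5; each ground truth is assigned to one scale by box
size and to the cell containing its center. Distribution-focal-loss
internals are out of scope here, so the DFL gain is accepted in
configuration but unused by this trainer. The reference training recipe
(500 epochs, batch 16, 640², SGD momentum 0.937, weight decay 0.001) is
carried in configuration; the smoke-training check itself runs 2 epochs on
8 synthetic 128² scenes with batch 4 and lr 0.01 — problem sizes chosen so
the full forward/backward graph (all 34 layers, including MSLA, CMUNeXt,
HyperACE and the fusion tunnels) is exercised end to end with a strictly
decreasing loss, which is a machinery check, not a claim about converged
accuracy.

## Known limitations

* Composite-block interiors (C3k2_MSLA, A2C2f, HyperACE, Detect) are this
  package's own designs; only their wiring contracts and the plain-Conv
  parameter convention are pinned to the reference table.
* The trainer is single-process, full-precision CPU numpy; it is built for
  correctness checks and small experiments, not throughput.
* NMS is a simple per-class greedy pass; no test-time augmentation.
* Non-square mosaics, overlapping/padded tilings, and area-stratified
  COCO-style AP are out of scope.
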