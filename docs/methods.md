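# Methods

## The detection problem

Sun-dried kelp is laid out on sand in dense, overlapping, elongated strips
and photographed from a UAV at 3–40 m. Three properties make this hard for
a stock one-stage detector: objects shrink with altitude (small-object
regime), neighbouring strips overlap so heavily that even human annotators
label some groups with a single *collective* box, and unlabeled distractors
(washed-up weed, debris) sit in the same scenes. The package implements a
YOLOv5-n-derived family of detectors addressing these, plus the synthetic
data needed to verify every stage without the original imagery.

## Architecture

The baseline is the v6.0 P5 layout at n-scale (width multiple 0.25, depth
multiple 0.33): a CBS/C3/SPPF backbone, an FPN+PAN neck, and three
prediction heads at strides 8/16/32 with three anchors each. Four
modifications define the variant ladder (`baseline`, `model1`, `model2`,
`model3`, `kyolo`):

* **Stride-4 head** (`model1`): a 3×3 CBS after the second neck C3, a 2×
  nearest upsample, concatenation with the first backbone C3 output, a C3,
  and a fourth detect conv on the resulting 160×160 grid (at 640 input).
  The PAN down-path is extended symmetrically. The kernel size of the
  inserted CBS is an open choice; 3×3 is the CBS default and is also the
  choice consistent with the family's published compute figures (a 1×1
  lateral would add only ~17% FLOPs rather than the expected ~22%).
* **I-CBAM** (`model2`): one block immediately before each of the four
  head convolutions. Relative to CBAM, exactly two changes: Hardswish
  replaces ReLU inside the shared channel-attention bottleneck, and the
  spatial branch becomes conv(7×7, 2→1) → batch-norm → Hardswish instead of
  conv → sigmoid. The channel branch's final sigmoid is retained (only the
  stated changes are made); it is configurable. Consequences worth knowing:
  spatial attention weights live in [−0.375, ∞), not (0, 1), and any
  pre-activation ≤ −3 gates its pixel to exactly 0. Bottleneck reduction 16
  and kernel 7 follow CBAM convention (unstated upstream).
* **GSConv neck** (`model3`): every neck CBS (lateral 1×1s, the inserted
  3×3, and the PAN downsampling 3×3s) becomes GSConv — dense conv to half
  the output channels, 5×5 depthwise conv producing the other half,
  concatenation, and a 2-group channel shuffle interleaving the halves.
  Backbone and detect convolutions are untouched. GhostConv (same skeleton
  without the shuffle) is provided for the lightweight-module comparison.
* **αS-IoU loss** (`kyolo`): a training-time change only; `model3` and
  `kyolo` are structurally identical.

Weight initialisation is Kaiming-normal for convolutions, BN weight 1 /
bias 0, seedable; detect-conv objectness biases start at the standard low
prior (log of ~8 expected objects over the grid). Batch-norm uses eps 1e−3
and momentum 0.03 for numerical comparability with the reference family.

## FLOP accounting

`count_flops` runs a real batch-1 forward pass at the requested input size
and sums k²·c_in/g·c_out·H_out·W_out multiply-accumulates over convolution
and linear layers, ×2 FLOPs per MAC, batch-norm folded, activations and
pooling free. At 640×640 with one class this yields 4.13 / 5.04 / 5.04 /
4.74 GFLOPs for baseline / model1 / model2 / model3-kyolo. The counted
I-CBAM overhead (~0.01 GFLOPs) is smaller than the 0.1 step the reference
table shows between its four-head and attention rows; the table's printed
granularity (one decimal) absorbs the difference.

## The box-loss family

All five losses share one broadcastable implementation (`bbox_loss`) that
runs on NumPy arrays and autodiff tensors alike. The S-IoU angle cost is
evaluated through the identity

    1 − 2 sin²(arcsin(s_ch/d) − π/4) = 2·s_cw·s_ch / d²,

which is algebraically exact for s_cw, s_ch ≥ 0, avoids the arcsin
branch, and is smooth at d → 0 when guarded with eps (coincident centers
give angle cost 0 — there is no direction to penalize). Two printed-formula
ambiguities are resolved as follows, both configurable:

* The shape-cost height term uses |H − H_gt| / max(H, H_gt) — the
  width-term formula is printed twice upstream, an evident typo — and both
  terms take absolute differences so the cost is sign-independent.
* The S-IoU total defaults to the *standard* grouping
  1 − IoU + (Δ + Ω)/2, where the angle cost enters only through
  γ = 2 − Λ inside Δ. A `paper-literal` grouping additionally adds Λ as a
  third term inside the halved penalty, for readers of the flattened
  printed equation; neither is asserted to be the upstream authors' intent.

θ defaults to 4 and is clamped to [2, 6]; α defaults to 3 for αS-IoU and 1
otherwise, and α = 1 reproduces S-IoU bit-for-bit. C-IoU's aspect-ratio
weight is kept differentiable (not detached), so autodiff gradients equal
finite differences for every kind — the suite checks all five to 1e−4
relative at random non-degenerate pairs.

IoU uses intersection / max(union, eps) so identical boxes give exactly 1
and every loss kind exactly 0 on a perfect match.

## Synthetic scenes

`generate_scene` is a pure function of its spec (seed included):

* **Background**: sand base colour modulated by low-frequency Gaussian
  noise (σ = size/8) plus per-pixel grain (`noise_level`, default 0.03).
* **Strips**: per scene, `n_strips` ∈ [8, 20] curved ribbons with aspect
  ratio 3–8 and length set by the altitude regime — close (3–10 m):
  0.28–0.55 of the image side; medium (10–25 m): 0.12–0.28; long
  (25–40 m): 0.05–0.12; `mixed` samples a regime per strip. With
  probability `overlap_prob` (default 0.5) a strip is dropped near an
  existing one, inducing overlap. Placement retries up to 10 times to stay
  in bounds; failures are counted in provenance, not silently lost.
* **Collective labels**: strips whose box IoU exceeds `merge_iou` (default
  0.4; no value is stated upstream, this is the generator's free
  parameter) are grouped by union-find and labeled with one enclosing box.
* **Distractors**: Poisson(`debris_rate`) greenish blobs, never labeled.

Augmentation covers the three stated operations. Additive noise leaves
boxes untouched. Rotation defaults to quarter turns so boxes transform
exactly ((cx, cy, w, h) → (1 − cy, cx, h, w) per clockwise turn);
arbitrary-angle rotation with re-fitted enclosing boxes sits behind a flag
because re-fitting inflates boxes of elongated objects. Masking paints 1–3
grey rectangles and drops any label whose visible pixel fraction falls
below 25%. `make_dataset` writes PNGs, YOLO-txt labels (6-decimal
normalized center-size; optional Pascal VOC XML with 1-based pixel
corners), and a manifest YAML, split round(0.7·n) / round(0.2·n) /
remainder — the 7:2:1 convention (2190 → 1533/438/219). The upstream
dataset was half originals, half augmented copies; `make_dataset` generates
fresh scenes by default and `augment` is available for composing such
mixtures.

What the generator does *not* model: photographic texture of real kelp,
lighting/shadow variation, camera optics and motion blur, and annotation
noise. Tests passing on these scenes therefore demonstrate that the
pipeline's machinery is correct and that the model class can fit the
geometric structure of the problem — not that the reported real-data
accuracy transfers.

## Training and evaluation

Target assignment follows the v6.0 convention: a ground-truth box is kept
for an anchor when max(ratio, 1/ratio) of width and height is < 4, and is
placed at its center cell plus the up-to-two neighbouring cells nearest the
center. Decoding: center = 2σ(t) − 0.5 + cell, size = (2σ(t))²·anchor.
The loss is box_weight · (mean box loss of the configured kind) +
obj_weight · Σ_heads balance_s · BCE(objectness), with balance weights
4.0/1.0/0.4/0.1 for strides 4/8/16/32 (extending the 3-head 4.0/1.0/0.4
downward); the class term vanishes for one class. Objectness targets at
assigned cells are (1 − gr) + gr·IoU with the decoded box (detached); gr
(`iou_aware_obj`) defaults to 1, the IoU-aware convention.

`TrainConfig` defaults follow the reference schedule: 200 epochs, 3
warm-up epochs at momentum 0.8 then 0.937, fixed lr 0.001, 640×640 input,
mosaic on. Anchors can be refitted to a dataset by k-means under the
1 − IoU distance (genetic refinement is out of scope); clusters are sorted
by area and assigned smallest-stride-first.

Evaluation: detections above a 0.001 confidence floor go through greedy
NMS (IoU 0.45, ties broken by score then index). AP is the 101-point
interpolated area under the precision–recall curve; the curve is evaluated
only at distinct score cuts, and equal-score detections match ground truth
in order of their best IoU — together this makes AP deterministic and
independent of detection storage order, a property plain COCO matching
lacks for ties. mAP@0.5:0.95 averages thresholds 0.50–0.95 in 0.05 steps;
with one class mAP = AP. Reported precision/recall use IoU 0.5 at a 0.25
confidence threshold. Precision is TP/(TP+FP) — the printed upstream
formula divides by TP+TN, but no true-negative count exists in detection
and the surrounding prose defines precision correctly.

## The scaled-down training check

Full-scale training (2190 real images, 200 epochs, GPU) is out of reach,
so detection quality is covered by a parameter-recovery property: the full
`kyolo` variant, trained from scratch on 200 easy synthetic scenes (large,
well-separated strips) must reach mAP@0.5 ≥ 0.5 on the held-out split for
a majority of 3 seeds. The smoke schedule was chosen by observing training
dynamics at this scale and then frozen: 96 px input, 50 epochs, batch 4,
lr 0.03 with cosine decay to 0.003, box weight 0.35, mosaic off, EMA
weights for evaluation, anchors fitted to the training labels, and the
objectness target annealed from gr = 0.5 to gr = 1 over training.
From-scratch optimisation at tiny batch sizes needs the larger lr and box
weight; a pure-IoU objectness target (gr = 1) from the start stalls early
training because decoded boxes are still random and the score signal
collapses to zero, while ending at gr = 1 calibrates scores to box quality
and down-ranks loosely localized duplicates. The check runs in ~4–5
minutes per seed on one CPU; the seed loop stops as soon as the majority
verdict is decided.

## Numerical and engineering notes

* The autodiff engine is float32 by default and dtype-preserving: float64
  inputs stay float64, which is what the finite-difference gradient
  contracts exercise. Convolution is evaluated tap-by-tap (one batched
  matrix product per kernel offset), so forward and both backward passes
  run through BLAS without an im2col buffer.
* SPPF's three chained stride-1 5×5 max-pools reproduce parallel 5/9/13
  pooling exactly; the suite asserts equality against an SPP block sharing
  weights.
* Decoded widths can underflow to exactly 0 through the float32 sigmoid;
  the prediction path clamps sizes at 1e−9 before NMS, and the loss path
  guards the detached IoU used for objectness targets the same way.
* NaN in any loss component raises immediately with the component values
  in the message; training aborts rather than continuing from a poisoned
  state.

## Known limitations

* Inference speed is not meaningful here (NumPy, single thread); the
  package reproduces compute *counts*, not wall-clock inference times.
* The synthetic scenes are statistically, not visually, faithful; absolute
  metric values on them say nothing quantitative about real kelp imagery.
* Multi-class support is plumbed through (class BCE, per-class decoding)
  but untested beyond the single-class use the problem calls for.
* mAP values from this evaluator can differ from other toolkits' in the
  third decimal because of the distinct-cut PR curve and deterministic tie
  handling described above.
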