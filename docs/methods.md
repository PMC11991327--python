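# Methods

## The model

`citrusdet` implements a lightweight single-stage leaf-disease detector in
the YOLOv8-n family, with two structural modifications aimed at citrus
lesion imagery:

1. **DR modules** replace every C2f feature block (backbone layers 2/4/6/8,
   neck layers 12/15/18/21).  A DR module is a GELAN-style stage: a 1×1
   in-conv projects to `c3` channels which are chunked into two halves; the
   second half passes through two sequential stages, each a CSP submodule
   (`DRBNCSP`) followed by a 3×3 stage conv; the two halves and both stage
   outputs are concatenated and fused by a 1×1 out-conv.  Inside the CSP
   submodule, the bottleneck's spatial mixing is a dense 3×3 conv followed
   by a **dilated-reparam block**: a depthwise 9×9 convolution trained in
   parallel with depthwise (k=5, r=1), (k=3, r=2) and (k=3, r=3) dilated
   branches, each batch-normalized.  Because a dilated convolution equals a
   non-dilated convolution with a zero-interleaved sparse kernel, the whole
   block collapses after training into a single depthwise 9×9 convolution
   (`reparam.merge_branches`), keeping the large receptive field at small
   deploy cost.

2. **A shared-parameter head** replaces the decoupled two-tower head.  Per
   scale, a partial convolution (3×3 over the first quarter of the
   channels, the rest passed through untouched) and a 1×1 channel-fusion
   conv form one stem whose output both task branches *share*; the
   classification and regression predictions are then single 1×1 convs,
   with a learned per-scale scale factor on the regression output and the
   usual DFL decode (expected value over 16 bins per box side).  Sharing
   the stem between the two tasks is what removes the decoupled head's
   duplicated 3×3 towers; it is the dominant saving of the design.

## Frozen architecture hyper-parameters

The DR stage widths are free parameters of the topology.  They are frozen
in `model.DR_SITES` as `(c3, c4, c5, n)` per site:

| layer | in→out    | c3  | c4 | c5 | n |
|-------|-----------|-----|----|----|---|
| 2     | 32→32     | 26  | 8  | 6  | 1 |
| 4     | 64→64     | 12  | 14 | 14 | 3 |
| 6     | 128→128   | 64  | 32 | 32 | 1 |
| 8     | 256→256   | 66  | 70 | 70 | 1 |
| 12    | 384→128   | 64  | 32 | 32 | 1 |
| 15    | 192→64    | 32  | 16 | 16 | 1 |
| 18    | 192→128   | 64  | 32 | 32 | 1 |
| 21    | 384→256   | 150 | 40 | 80 | 2 |

These widths were chosen once so that the deployed model's per-layer and
total parameter/FLOP profile reproduces the published accounting of the
reference design (layer 4: 173.77 MFLOPs; layer 6: 54.75 K params;
layer 21: 225.73 K params / 179.87 MFLOPs; totals 1.56 M params and
3.3 GFLOPs, i.e. 48.17 % fewer parameters and 59.26 % less computation
than the 3.01 M / 8.1 G baseline).  They are part of the versioned model
config, not tunables.

## Profiling conventions

* Parameters are counted on the **deployed** network: every BN folded into
  the preceding conv (weights + one bias per output channel), every
  dilated-reparam block merged to its single 9×9 depthwise kernel, plus
  the head's frozen 16-entry DFL projection and the three regression
  scale factors.
* FLOPs = 2 × multiply-accumulates of the convolutions, computed
  analytically from the conv weight shapes at a stated square input
  (default 640); biases, activations and elementwise ops are excluded
  (sub-0.1 % at this scale).  Parameter counts are input-size invariant;
  FLOPs scale with spatial area.
* Head profile rows at layer 22 depend on the class count.  Model totals
  are quoted for the six-class task; the head-only comparison rows
  (199.81 K vs 896.80 K, 453.27 M vs 3.62 G) correspond to the 80-class
  default head configuration, whose classification tower is
  `max(ch0, min(nc, 100))` = 80 wide in the decoupled baseline.

## Losses and assignment

Box loss is complete-IoU: `1 − IoU + ρ²/c² + αv` with
`v = (4/π²)(arctan(w_g/h_g) − arctan(w/h))²` and `α = v/(1−IoU+v)` treated
as a constant weight.  Box-side offsets are trained with the distribution
focal loss over the two integer bins bracketing the continuous
(stride-normalized) target, clipped to `[0, reg_max−1−0.01]`.
Classification is independent per-class binary cross-entropy on logits
with **binary** targets (the assigned anchor's class is 1), natural
logarithms, probability clamp 1e-7.  The total is
`7.5·box + 1.5·DFL + 0.5·cls`.

Assignment is task-aligned: alignment metric `s^0.5 · IoU^6` over anchors
whose centre lies inside the box, top-10 anchors per ground truth,
conflicts resolved toward the larger metric.  Box and DFL terms are
weighted averages over assigned anchors (weights = normalized alignment
scores); the classification sum is normalized by the number of assigned
anchors.

## Training

Defaults mirror the reference recipe (SGD, lr0 0.01, lrf 0.01, momentum
0.937, weight decay 5e-4, 200 epochs, batch 32, 640 px, early-stopping
patience 50 on validation mAP50).  Three implementation choices matter on
small desk-scale runs:

* Batch-norm backward goes through the batch statistics (the constant-
  statistics shortcut makes gradient norms explode through the 20+ layer
  stack).
* Prediction biases start at a 0.01 class prior and one stride-unit box
  offset, the standard dense-detector initialization.
* After training, BN running statistics are recalibrated with a few
  forward passes at high momentum, since tiny-run running averages lag the
  final weights.

For the desk-scale learnability check the package uses Adam (lr 0.01,
linear decay to 0.1, one warmup epoch): with O(100) gradient steps the
per-layer gradient scales span two orders of magnitude and plain SGD makes
no visible progress, while Adam reaches useful detections.  SGD remains
the default for full-scale runs.

## Synthetic data

`synth.render_scene` draws leaf-like backgrounds (green base, smooth
noise, faint veins) and six programmatic lesion morphologies matching the
field labelling scheme: `a` punctate dark clusters, `c` concentric ringed
discs, `h` asymmetric yellow mottling, `m` dense black micro-dots, `n`
diffuse *low-contrast* chlorosis (hardest by construction), `p` dark-
rimmed perforations.  Boxes tightly enclose drawn pixels.  Default class
frequencies mimic the study's imbalanced distribution (canker at 160 of
6050); the 8:1:1 stratified splitter floors the train fraction (6050 →
4840 train) and alternates the remainder val-then-test.  Everything is
deterministic under a master seed.

**Easy mode** (the training smoke fixture) uses one large lesion per
image, a plain background, uniform class sampling and a linearly
separable per-class palette.  It probes end-to-end learnability — data
loading, assignment, loss, optimization, decoding — not robustness: the
realistic mode's confusable morphologies (a/m both dark-punctate, h/n
both yellowing) and class imbalance are exactly what it removes, so a
passing smoke run says nothing about field accuracy.

The smoke check trains the DE variant from scratch on 200 easy images at
96 px for 10 epochs (batch 8) on three seeds and requires strictly
decreasing epoch losses after epoch 2 plus held-out mAP50 ≥ 50 % on a
2-of-3 majority; evaluation uses a 0.01 confidence floor, the standard
practice for AP computation.  The 96 px size is the package's scale
choice for a pure-NumPy engine; the box/feature geometry (lesions of
0.28–0.4 image widths, stride-8/16/32 anchors) matches larger inputs.

## Evaluation

Matching is confidence-greedy to the highest-IoU free same-class ground
truth at the stated threshold.  AP uses 101-point interpolated
integration; mAP averages classes that have ground truth and is reported
in percent; mAP50-95 averages IoU 0.50–0.95 in 0.05 steps.  The TIDE
taxonomy classifies each false positive by its best overlap — Cls
(≥0.5, wrong class), Dupe (≥0.5, right class, ground truth already
claimed), Loc (0.1–0.5, right class), Both (0.1–0.5, wrong class), Bkg
(<0.1) — with boundary 0.5 assigned to the ≥0.5 bands; Miss counts ground
truths with no overlap ≥0.1 from any detection.  Reports carry both raw
counts and counts per 100 images.  The right/missing/error tally runs at
IoU 0.45.

## Numerical choices and limitations

* Merge tolerance for reparameterized blocks: 1e-4 in float32; in float64
  the algebra agrees to ~1e-13 (the merged kernel is kept in float64 and
  cast to the input dtype at forward time).
* NMS ties at equal confidence break toward the lower box index;
  detection confidence is the sigmoid class score (no objectness).
* Zero-denominator conventions: precision/recall return 0; classes with
  no ground truth are excluded from mAP.
* The engine is single-threaded NumPy: correctness-first, suitable for
  desk-scale experiments and unit-verifiable algebra, not for full-scale
  training; throughput, latency and FPS are out of scope.
* `Conv` uses BN eps 1e-3, momentum 0.03, SiLU activation throughout.
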