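# Methods

## Problem and model

`hhbsnet` segments facial photographs into six classes — background,
forehead (ET), chin (XB), left/right facial areas (LF/RF) and melasma
lesions (HHB). Melasma lesions are low-contrast, irregularly shaped and
soft-edged, so the architecture combines three mechanisms that target
exactly those difficulties:

1. **Infusion.** The backbone yields four feature levels at strictly
   increasing strides. The deepest level is bilinearly upsampled to the
   shallowest level's resolution, concatenated (shallow first) and
   projected by a 1×1 convolution to the trunk width, mixing texture
   detail with semantics before any attention is applied.
2. **GCSA.** Channel attention is a two-layer perceptron
   (C → C/4 → C, ReLU between, sigmoid after) applied along the channel
   axis *independently at every spatial position* — there is no global
   pooling in this gate; the permutation that moves channels to the
   last axis is an implementation detail with no effect on the result.
   A 4-group channel shuffle (reshape to (groups, C/groups), transpose,
   flatten) then interleaves channels, and a 7×7 convolutional gate
   (C → C/4 bottleneck, batch norm, zero padding 3 so the element-wise
   product is defined) re-weights positions. The spatial gate
   multiplies the *shuffled* map, not the block input.
3. **MCF.** Five parallel branches (1×1 conv; depthwise-separable 3×3
   convs at dilation rates 6/12/18 with padding equal to the rate;
   global average pool → 1×1 conv → broadcast) are concatenated and
   projected 5C → C by a plain 1×1 convolution. Channel and spatial
   calibration act on that projected C-channel map — applying them to
   the 5C concatenation would make the final shapes inconsistent. The
   calibrated maps are summed with the projected map (residual; the
   residual can be switched off via `NetworkConfig.mcf_residual`) and
   passed through a final 1×1 convolution, C → C.
4. **Global feature fusion** injects a pooled image-level descriptor
   (1×1 conv on the global average) back into every position through
   concatenation and a second 1×1 convolution.

A 1×1 classifier head maps the trunk to class logits, bilinear
upsampling restores input resolution, and a per-pixel softmax produces
the probability map. Masks are the per-pixel argmax with ties broken
toward the lower class index. One GCSA and one MCF instance sit on the
trunk; the block order backbone → infusion → GCSA → MCF → global fusion
is fixed in `HHBSNet` and recorded in the config.

Normalization choices inside the blocks: the channel-attention MLP and
the MCF calibration layers carry biases and no normalization; batch
norm appears in the spatial-attention convolutions and after each
convolutional MCF branch. The pooling branch of the MCF operates on a
1×1 map whose batch statistics are degenerate (zero spatial variance;
undefined for batch size 1), so that branch uses conv + ReLU without
batch norm. Batch norm uses batch statistics in training mode and
running buffers (momentum 0.1) in inference mode.

## Objective

`L = λ·L_CE + (1−λ)·L_FL` with `L_FL = −α(1−p_t)^γ log p_t`, averaged
over pixels. λ, α and γ are exposed in `LossConfig`; the defaults
λ = 0.5, α = 0.25, γ = 2 are the conventional focal-loss settings, with
an even split between the two terms. Probabilities are clipped at
1e-7 before logarithms. With γ = 0, α = 1 the focal term reduces
exactly to cross-entropy, which the tests assert.

## Numerical engine

No GPU framework is used: the package carries a small reverse-mode
autodiff engine over float64 numpy arrays (`hhbsnet.autodiff`) and a
layer library (`hhbsnet.nn`) with Kaiming-uniform initialization and
SGD + classical momentum. Convolution is implemented by explicit
kernel-tap slicing and grouped einsum (supporting stride, dilation,
groups, zero or circular padding); bilinear resizing uses half-pixel
centre sampling so constants are preserved exactly; log-softmax is
max-shifted for stability. Every backward rule is validated against
central finite differences in `tests/test_autodiff.py`, and the
convolution forward against a nested-loop oracle. The circular
("wrap") padding mode exists to make the dilated branches' translation
equivariance testable on periodic inputs; networks use zero padding.

Tie handling: the channel-max reduction in the MCF spatial calibration
splits its gradient equally across tied maxima (ties are measure-zero
for continuous inputs).

## Training protocol

SGD with momentum 0.9, initial learning rate 7e-3, batch size 8,
180 epochs, and step decay `lr(e) = lr₀ · f^⌊e/p⌋` — the decay factor
and period are not fixed by the protocol, so the defaults are f = 0.1
every p = 60 epochs, both configurable. Augmentation applies each flip
(horizontal, vertical) with probability 0.5 and a random crop at
relative scale drawn from [0.7, 1.0] (the crop range is the package's
choice), resized back with bilinear/nearest resampling for
image/mask. The best checkpoint is selected by validation MIoU.

The capability probe (`fit_full_batch`) uses plain full-batch steps at
lr 0.03 on the 16-channel tiny-backbone configuration: 350 steps on
eight 64×64 scenes drive training MIoU above 0.9, which demonstrates
that the assembled architecture, objective and gradients can jointly
fit the face-layout and lesion geometry. Problem sizes throughout the
tests (64×64 scenes, trunk widths 8–16) were chosen as the smallest at
which every class is populated and the trunk retains enough resolution
for lesion boundaries.

## Evaluation protocol

All seven metrics (MIoU, pixel accuracy, macro F1, mean recall,
precision, Dice, specificity) derive from one confusion matrix
accumulated over every pixel of the evaluated collection. Per-class
quantities with undefined denominators — e.g. IoU for a class absent
from both reference and prediction, which happens on tiny scenes — are
skipped by the macro means. Macro Dice from global counts is
algebraically identical to macro F1 (the tests assert it); the
lesion-focused figure reported separately is the per-image HHB Dice
averaged over images, which is the variant that is meaningfully lower
than F1 when lesions are small relative to the face. Specificity is
the macro mean of per-class TN/(TN+FP). One-vs-rest ROC/AUC sweeps all
thresholds per class channel with trapezoidal integration (tie groups
collapsed); classes without both positives and negatives report a
missing AUC rather than 0. The paired t-test uses the exact t
distribution with df = n−1 and raises a typed error on zero-variance
differences instead of returning ±∞. Run aggregation reports mean ±
sample standard deviation (n−1).

The evaluation driver refuses a collection whose basenames overlap the
training manifest unless explicitly overridden.

## Synthetic scenes

The generator emulates the documented difficulties of clinical melasma
photography, not its appearance in detail. A scene is an elliptical
face (jittered axes ≈ 0.32/0.42 of the image) on a dark backdrop,
partitioned into ET (above a jittered cut ≈ 0.34 of face height),
LF/RF (middle, split at a jittered midline) and XB (below ≈ 0.78).
Lesions are thresholded smoothed-noise blobs (irregular outlines)
placed strictly inside a 10%-eroded face ellipse; the mask records the
crisp support while the image receives a soft-edged brownish darkening
(Gaussian alpha, default σ = 1.5 px) at a small contrast offset
(default 0.12), under a linear illumination gradient (default maximum
relative slope 0.25 across the image), a few specular highlights
(default 3) and additive Gaussian noise (default sd 0.02). Defaults of
2–6 lesions per face keep the lesion class rare relative to background,
as in the clinical setting. Everything is deterministic given the spec
seed.

What passing tests on these scenes shows: the pipeline is correct
end-to-end (shapes, gradients, metrics, bookkeeping) and the
architecture can fit low-contrast irregular lesions under lighting
confounds. What it does not show: performance on real VISIA
photographs — synthetic faces lack skin texture, hair, pose variation
and the full melasma colour distribution, so no clinical metric values
should be read off these experiments.

## Known limitations

* CPU-only float64 execution is orders of magnitude slower than a GPU
  framework; the intended scale is desk-scale experiments and testing,
  not 512×512 × 180-epoch clinical training runs.
* The inverted-residual backbone trains from random initialization;
  pretrained weights can be supplied as a local `.npz` but no weights
  ship with the package.
* MIoU on tiny scenes depends on which classes are present; the
  absent-class skipping rule makes small-scene MIoU slightly optimistic
  relative to the fixed-denominator variant.
* The 8:1:1 split is by item index with a seeded shuffle; no
  patient-level stratification is modelled.
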