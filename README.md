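# hhbsnet

Lightweight multi-class semantic segmentation of facial melasma.

Melasma presents as symmetric brown facial patches with blurred,
irregular borders and very low contrast against normal skin; lighting
gradients and specular reflections make automated delineation harder
still. `hhbsnet` implements a compact segmentation network designed for
this problem, together with its complete training, evaluation and
statistics protocol, and a synthetic facial-scene generator so the whole
pipeline can be exercised end-to-end without access to clinical
photographs.

The label schema has six classes: `BACKGROUND`, `ET` (forehead), `HHB`
(melasma lesion), `XB` (chin), `LF`/`RF` (left/right facial areas).

## The model

The network is a single shape-preserving trunk over a four-level
convolutional backbone:

```
backbone -> infusion(first, last level) -> GCSA -> MCF
         -> global feature fusion -> 1x1 classifier -> upsample -> softmax
```

* **GCSA (Global Channel–Spatial Attention).** A per-position channel
  gate `F_c = σ(MLP(F)) ⊙ F` (bottleneck C → C/4 → C, applied along the
  channel axis independently at every pixel), a 4-group channel shuffle
  that interleaves channels across groups, and a spatial gate
  `F_s = σ(BN(Conv₇ₓ₇(ReLU(BN(Conv₇ₓ₇(F_sh)))))) ⊙ F_sh`.
* **MCF (Multi-scale Cavity Fusion).** Five parallel branches — a 1×1
  conv, three depthwise-separable 3×3 convs dilated at rates 6, 12, 18
  ("same" padding), and a global-average-pool branch — concatenated to
  5C channels and projected back to C, then recalibrated by a channel
  gate `w_c = σ(FC₂(ReLU(FC₁(avgpool(F)))))` and a spatial gate
  `w_s = σ(Conv₁ₓ₁([mean_c(F); max_c(F)]))`, and fused residually:
  `F_out = Conv₁ₓ₁(w_c⊙F + w_s⊙F + F)`.
* **Hybrid objective.** `L = λ·L_CE + (1−λ)·L_FL` with
  `L_FL = −α(1−p_t)^γ log p_t`, defaults λ = 0.5, α = 0.25, γ = 2,
  addressing the extreme background/lesion pixel imbalance.

Training uses SGD (momentum 0.9, initial lr 7e-3, step decay) with
on-the-fly flip/crop augmentation. Evaluation reports MIoU, pixel
accuracy, macro F1, mean recall, precision, Dice and specificity from a
single global confusion matrix, plus per-image lesion Dice, one-vs-rest
ROC/AUC per class, mean ± sd aggregation over repeated runs, and paired
t-tests between models.

The network, including convolution/batch-norm/resize gradients, runs on
the package's own numpy reverse-mode autodiff engine
(`hhbsnet.autodiff`, `hhbsnet.nn`); every backward rule is verified
against finite differences in the test suite.

## Worked example

```python
import numpy as np
import hhbsnet as hb
from hhbsnet import nn

# 8 synthetic 64x64 facial scenes (the desk-scale study conditions)
records = hb.generate_dataset(8, hb.SceneSpec(image_size=64), seed=7)
images = np.stack([r["image"].astype(np.float64) for r in records])
masks = np.stack([r["mask"] for r in records])

nn.manual_seed(7)
net = hb.HHBSNet(hb.NetworkConfig(backbone="tiny", working_width=16,
                                  input_size=64))
losses = hb.fit_full_batch(net, images, masks, steps=350, lr=0.03,
                           loss_config=hb.LossConfig(lam=0.5, alpha=0.25,
                                                     gamma=2.0))
cm = np.zeros((6, 6), dtype=np.int64)
for img, msk in zip(images, masks):
    cm += hb.confusion_matrix(net.predict_mask(img), msk, 6)
report = hb.segmentation_metrics(cm)
print(f"final loss {losses[-1]:.4f}  train MIoU {report.miou:.4f}")
```

prints

```
final loss 0.0179  train MIoU 0.9568
```

i.e. the hybrid loss has fallen from ≈ 1.8 (chance level for six
classes is ln 6 ≈ 1.79 under cross-entropy) to 0.018, and the network
reproduces the eight training masks at 95.7% mean IoU — it has the
capacity to learn the face-region layout and the irregular lesion
blobs. Held-out scenes from the same generator evaluate lower (see the
acceptance script), as expected for eight training images.

A shell workflow is available through the console script:

```sh
hhbsnet synth -n 20 --size 128 --seed 0 --out-dir data/
hhbsnet train --data-dir data/ --out-dir run/ --backbone tiny --epochs 20
hhbsnet evaluate --checkpoint run/best.npz --data-dir data/ --out-dir eval/
hhbsnet predict --checkpoint run/best.npz --image data/scene_0000.png --out-dir pred/
```

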