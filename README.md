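# vesselseg

Retinal vessel segmentation with a serial Transformer + CNN U-Net.

Segmenting the vessel tree in fundus photographs is a prerequisite for
grading diabetic and hypertensive retinopathy: vessel thickness, curvature
and density carry the clinical signal, and the hard part is the capillaries
— curvilinear structures one or two pixels wide in low-contrast images.
Convolutions capture such local detail but have small receptive fields;
self-attention models long-range context but misses fine structure.  This
package implements a hybrid that runs a four-stage Transformer front end
over a multi-resolution patch pyramid (64/32/16/8 px) and feeds each
stage into a convolutional U-Net encoder–decoder for fine-grained
reconstruction.

The attention unit is a **TPA block**: spatially-reduced multi-head
self-attention (queries from the full token grid, keys/values from a
stride-`s` reduced map, per-head logits `Q·Kᵀ/√d_k` mixed across heads by a
1×1 convolution) followed by **criss-cross position attention** — each
pixel attends to the `H+W−1` positions in its row and column — applied
twice with shared weights so that information propagates between every
pair of pixels.  Shallow-information fusion pools all encoder outputs into
a pyramid-pooling bottom module, and the decoder restores resolution with
additive residual skips.  Training minimizes the Dice loss

    DiceLoss = 1 − (2·Σ p·g + w) / (Σ p + Σ g + w),      w = 1e−5

over 64×64 patches; evaluation stitches grid-patch predictions into
whole-image probability maps and scores Dice, accuracy, sensitivity,
specificity, precision and ROC/PR areas inside the field of view.

Everything runs on plain numpy through a small reverse-mode autodiff
engine included in the package (`vesselseg.nn`); no GPU framework is
required.  A seeded synthetic-fundus generator provides images with known
vessel ground truth so the whole pipeline is testable without downloading
the DRIVE/STARE/CHASE DB1 datasets (loaders for their directory layouts
are included).

## Worked example

Train the desk-profile network (same topology as the full model at ~334 k
parameters) to reconstruct the vessels of 8 patches from one synthetic
fundus image — about 3 minutes on one CPU:

```python
import numpy as np

from vesselseg import (
    MTPAUnet, SynthConfig, TrainConfig, desk_config, dice_coefficient,
    extract_patches, generate_vessel_mask, preprocess, render_sample,
)
from vesselseg.nn.tensor import set_default_dtype
from vesselseg.training import fit_patches

set_default_dtype("float32")          # training runs in single precision

cfg = SynthConfig(seed=1)             # one 128x128 synthetic fundus image
sample = render_sample(generate_vessel_mask(cfg), cfg)
enhanced = preprocess(sample)         # fuse -> normalize -> CLAHE -> gamma

pairs = extract_patches(enhanced, sample.vessel_mask, sample.fov_mask, n=8, seed=3)
pyramids = [p for p, _ in pairs]
labels = np.stack([lab for _, lab in pairs])

model = MTPAUnet(desk_config(seed=0))
history = fit_patches(
    model, pyramids, list(labels),
    TrainConfig(batch_size=8, epochs=200, max_steps=200, val_fraction=0.0, seed=0),
)
probs = model.predict_pyramids(pyramids)
print(f"final Dice loss : {history['train_loss'][-1]:.3f}")
print(f"training Dice   : {dice_coefficient(probs >= 0.5, labels > 0.5):.3f}")
```

Output from this exact snippet:

```
final Dice loss : 0.171
training Dice   : 0.845
```

The loss is `1 − soft Dice` over the training patches, so 0.171 means the
probability maps reproduce ~83% soft overlap with the vessel masks; the
training Dice is the pooled hard overlap after thresholding at 0.5.  A
run this short measures the optimization dynamics, not the architecture's
capacity — the same run crosses Dice 0.9 at roughly 300 steps.  For
multi-image training and whole-image evaluation use the
`VesselSegmenter` estimator (`fit`/`predict`/`score`) or the functions in
`vesselseg.training`; note that short Dice-only training runs are
sensitive to initialization (see `docs/methods.md`).

The same pipeline is scriptable from the shell:

```bash
vesselseg --seed 1 simulate --out data/ --n 6
vesselseg --seed 1 train --data data/ --checkpoint model.npz
vesselseg eval --data data/ --checkpoint model.npz
```

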