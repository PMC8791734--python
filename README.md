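# osteoseg

Osteosarcoma is the most common primary malignant bone tumor in children and
adolescents, and MRI is the standard modality for delineating it.  Reading the
600–700 slices a single examination produces is slow and subjective, and on
T1-weighted slices the tumor's gray values sit close to those of surrounding
muscle and edema.  `osteoseg` is a library + CLI that implements an automated
segmentation and measurement pipeline for single 2-D MRI slices:

1. **Slice curation** — a Mean-Teacher semi-supervised classifier (ResNet-7:
   six residual blocks + one fully connected head) splits a slice pool into
   *useful* (US) and *normal/difficult* (NS) slices, so a segmentation network
   can learn simple samples first.  The student minimizes
   `l = l1 + l2` with `l1` the cross-entropy on the labeled 70% and
   `l2 = ½ KL(P_s2 ‖ P_t2) + ½ KL(P_t2 ‖ P_s2)` the symmetrized-KL consistency
   with the teacher on the unlabeled 30%; the teacher tracks the student by the
   exponential moving average `θ_t′ = α θ_t + (1 − α) θ_s′`.
2. **Preprocessing** — a weighted between-class-scatter threshold
   (`T = argmax_g ρ₀ n_{<g}(μ − μ_{<g})² + ρ₁ n_{≥g}(μ − μ_{≥g})²`, with
   ρ₀ = 0.67, ρ₁ = 0.33), speck removal and hole filling, and restriction to
   the *credible region* — the bounding box of the bright body mask, outside
   which no tumor is assumed.
3. **Segmentation** — a depthwise-separable U-Net (SepUNet: four encoder
   levels of DoubleConv + SeparableBlock, four decoder levels with bilinear
   ×2 upsampling and skip concatenation), trained with the compound loss
   `L = α₁ L_BCE + α₂ L_Dice` (α₁ = α₂ = 0.5).  At inference the slice is
   presented at 0°/90°/180°/270° and the back-rotated probability maps are
   averaged with weights (0.4, 0.2, 0.2, 0.2).
4. **CRF refinement** — a grid conditional random field with
   intensity-modulated Potts pairwise potentials sharpens the blurred tumor
   boundary (mean-field or ICM inference).
5. **Area measurement** — the mask boundary is traced sub-pixel, resampled at
   1 mm, smoothed by an MCMC particle filter, boxed by its minimal
   circumscribed rectangle and tiled with 4 mm × 4 mm cells; fully covered
   cells contribute S_c = 16 mm² and partially covered cells are integrated by
   a composite Newton–Cotes (Boole) rule over a Lagrange interpolant of the
   crossing boundary:  `S_os = Σᵢ Sᵢ + M₁·S_c`.

The clinical dataset this pipeline targets is not distributable, so the
package ships a **phantom generator** producing T1-like slices (bright body,
low-contrast tumor blob, blurred boundary, noise) with exact ground truth:
mask, closed-form area, and US/NS label.  Every stage is tested against those
phantoms and against independent numerical oracles.

The networks run on a small numpy reverse-mode autodiff engine bundled with
the package (`osteoseg.nn`) — no GPU or deep-learning framework required.

## Worked example

```python
import numpy as np
from osteoseg import (PhantomSpec, generate_dataset, build_model, SepUNetConfig,
                      TrainSchedule, train_segmentation, PipelineConfig,
                      run_on_samples)
from osteoseg.sepunet import predict
from osteoseg.metrics import evaluate_masks

spec = PhantomSpec(image_height=64, image_width=64, pixel_spacing=1.0)
train = generate_dataset(spec, 50, seed=11)
test  = generate_dataset(spec, 10, seed=99)

model = build_model(SepUNetConfig(base_channels=8), seed=3)
train_segmentation(model, train,
                   schedule=TrainSchedule(epochs=20, batch_size=8, drop_fraction=0.7),
                   seed=5)

reports, agg = run_on_samples(test, model, PipelineConfig(pixel_spacing=1.0, seed=0))
print(f"held-out DSC {agg['DSC']:.3f}")
print(f"slice 0: S_os = {reports[0].S_os:.1f} mm^2 "
      f"(truth {test[0].true_area:.1f} mm^2)")
```

prints (exact values can vary slightly with BLAS builds):

```
held-out DSC 0.961
slice 0: S_os = 695.7 mm^2 (truth 749.6 mm^2)
```

i.e. the scaled-down network overlaps the true tumor at DSC ≈ 0.96 on unseen
phantoms; the measured area then inherits the segmentation error of the
predicted mask (here ~7 % on one slice), while the quadrature pipeline itself
recovers areas of clean masks to better than 1 %.

The same flow is available from the shell:

```sh
osteoseg phantom --n 10 --seed 1 --out data/
osteoseg area --mask data/slice_0000_mask.png --spacing-mm 0.5 --out area.json
osteoseg preprocess --image data/slice_0000.png --out pp/
```

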