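# dentseg

Two-stage slice-wise (2.5D) U-Net segmentation of the **missing-tooth
bone region** and the **implant region of interest** in dental CBCT
volumes — with a synthetic jaw-phantom generator, the full
surface-distance evaluation suite, and STL export for 3D printing.

It is written for researchers in dental/maxillofacial image analysis who
want a self-contained, reproducible re-implementation of this class of
implant-planning pipeline: every stage runs end-to-end on generated
phantoms, with no clinical data required.

## Method

A CBCT volume `V` (79 x 112 x 135 voxels, ~0.3 mm spacing) is windowed
to [−1000, 2000] HU and normalised to [0, 1]. Each stage applies a small
2D U-Net slice-wise:

* slices along an axis are resized to 24 x 24, the network predicts a
  probability image per slice, probabilities are resized back and
  stacked into a 3D volume, binarised at 0.5;
* the U-Net has four levels (three 2 x 2 poolings + bottleneck,
  24 → 12 → 6 → 3), two 3 x 3 conv + ReLU blocks per level, feature
  widths 32·2^ℓ = (32, 64, 128, 256), transpose-conv upsampling with
  skip concatenation, and a 1 x 1 sigmoid head;
* stage 1 segments the bone block spanning the edentulous gap from `V`;
  stage 2 segments the implant cylinder (4.1 mm x 10 mm) from
  `V ⊙ M₁`, the intensity volume masked by stage 1's output.

Predictions are scored with the 12-metric suite
(Dice = 2|A∩B|/(|A|+|B|), Jaccard, precision, recall, FPR, FNR,
volumetric dissimilarity |FN−FP|/(2TP+FP+FN), Hausdorff distance, MSD =
(1/N)Σd², StdSD, HD95, and volume error rate ||B|−|A||/|A|·100%), with
spacing-aware surface distances. Masks export to watertight binary STL
via padded marching cubes.

The network, its backward pass and the optimiser are implemented
directly on NumPy (im2col + BLAS); everything is seeded and
bit-reproducible. See `docs/methods.md` for the full model description
and design rationale.

## Worked example

```python
import numpy as np
from dentseg import (PhantomSpec, generate_cohort, CascadeSegmenter,
                     CascadeConfig, SliceUNet, window_hu, normalize_intensity)

spec = PhantomSpec(grid_shape=(40, 56, 68), voxel_spacing_mm=(0.6,) * 3)
cases = generate_cohort(10, spec, seed=3)            # deterministic cohort
train, test = cases[:8], cases[8:]

seg = CascadeSegmenter(stage1=SliceUNet(epochs=8, seed=0),
                       stage2=SliceUNet(epochs=8, seed=1),
                       config=CascadeConfig(), slice_step=2, seed=0)
seg.fit(train)

for c in test:
    vol = normalize_intensity(window_hu(c.volume))
    res = seg.predict(vol, truth=c)
    mb, mi = res.metrics["bone"], res.metrics["implant"]
    print(c.case_id,
          f"bone dice {mb.dice:.3f} ver {mb.volume_error_rate:.1f}%  "
          f"implant dice {mi.dice:.3f} ver {mi.volume_error_rate:.1f}%")
```

Output of this exact script (a deliberately tiny 8-case, 8-epoch run):

```
case008 bone dice 0.664 ver 48.0%  implant dice 0.626 ver 10.7%
case009 bone dice 0.545 ver 62.2%  implant dice 0.324 ver 77.7%
```

Interpretation: after only eight epochs on eight coarse phantoms the
cascade already localises both targets (Dice ≈ 0.3–0.66), though volume
errors (`ver`, the percent deviation of predicted from ground-truth
volume) are still large. The reference benchmark below — 24 training
cases, full resolution, 32 epochs — reaches bone-region Dice ≈ 0.9 with
~13 % volume error and implant Dice ≈ 0.8.

The same pipeline is scriptable from the shell:

```bash
dentseg phantom --n 10 --shape 79,112,135 --spacing 0.3 --seed 1 --out cohort/
dentseg train --stage bone    --data cohort/ --out models/ --epochs 32 --slice-step 5
dentseg train --stage implant --data cohort/ --out models/ --epochs 32 --slice-step 5
dentseg predict --volume cohort/case000_volume.nii.gz \
    --model1 models/bone_model.npz --model2 models/implant_model.npz --out pred/
dentseg evaluate --truth cohort/case000_bone_region.nii.gz \
    --pred pred/bone_mask.nii.gz --out report.csv
dentseg export-stl --mask pred/implant_mask.nii.gz --out implant.stl
```

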