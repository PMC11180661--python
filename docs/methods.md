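# Methods

## Problem setting

Planning a dental implant requires locating the edentulous (missing-tooth)
site in a CBCT scan and delineating the bone that will receive the
implant. `dentseg` implements a two-stage, slice-wise ("2.5D") approach:

1. **Stage 1 — missing-tooth bone region.** A small 2D U-Net segments,
   slice by slice, the block of alveolar bone spanning the edentulous gap
   from the whole volume.
2. **Stage 2 — implant ROI.** A second U-Net of identical architecture
   segments the implant-sized region (a 4.1 mm diameter x 10 mm cylinder,
   the standard implant geometry used for the ground truth) from an input
   conditioned on stage 1's output.

Both stages share one inference loop: cut the volume into 2D slices,
resize each slice to the network grid, predict a probability image,
resize it back to the native in-plane shape, and stack the slices into a
3D probability volume, binarised at 0.5.

## Synthetic phantoms

Clinical CBCT cohorts of this kind are not publicly distributable, so the
package ships a phantom generator that emulates their statistical shape
on the standardized 79 x 112 x 135 voxel grid at 0.3 mm isotropic
spacing:

* a horizontal bone slab (alveolar ridge, 13 mm thick, HU 1100) with
  soft tissue below (HU 40) and air above (HU −1000);
* an arch of 6 tooth-like cylinders (radius 1.5 mm, crowns 7 mm above
  the ridge, roots 11 mm into it, HU 1900) placed on a circular arc
  (radius 9 mm spanning 20°–160°), with exactly one interior tooth
  missing;
* ground truth 1: the slab bone spanning the gap plus a margin of one
  tooth-width per side, over the root-depth extent (any intruding
  neighbouring root is excluded — the target is bone);
* ground truth 2: the implant cylinder (4.1 mm x 10 mm) seated in the
  gap with its axis along the slab normal (grid axis 2), fully contained
  in ground truth 1 by construction;
* additive i.i.d. Gaussian noise (default SD 40 HU), then clipping to
  the skeletal window [−1000, 2000] HU, which makes windowing the
  identity on phantoms.

A voxel belongs to a solid iff its centre lies inside the continuous
solid; this makes voxel-count oracles exact (e.g. a 10 mm cylinder at
0.3 mm spacing occupies exactly the planes whose centres fall inside its
extent). Cohorts jitter arch and tooth radii by ±10 % (uniform) and vary
the missing-tooth position over the interior arch sites; default
geometry was chosen so that the containment invariant survives the
worst-case jitter. The phantoms deliberately omit beam hardening,
scatter, metal artifacts and anatomical detail (roots are cylinders, the
ridge is a slab): passing benchmarks demonstrates the pipeline's
correctness and learnability of the task class, not clinical
performance.

## Preprocessing

Intensities are clipped to [−1000, 2000] HU and mapped affinely onto
[0, 1]. The map is a *fixed-window global* normalisation rather than
per-volume min–max, so intensity scale is comparable across cases. Grid
standardisation (when inputs are not already 79 x 112 x 135) uses
trilinear interpolation for intensities and nearest-neighbour for masks,
rescaling the voxel spacing so physical extent is preserved.

## Network

Input 24 x 24 x 1 grayscale slices. Four resolution levels realised as
three 2 x 2 max-poolings plus a bottleneck (24 → 12 → 6 → 3): 24 is
divisible by two exactly three times, so "four levels" can only mean
three pooling steps with a fourth bottom level if shapes are to be
restored exactly. Two 3 x 3 same-padding convolutions + ReLU per level;
feature widths 32 · 2^ℓ = 32, 64, 128, 256; stride-2 transpose
convolutions (realised as zero-stuffing upsample + 3 x 3 convolution)
with ReLU on the decoder path; skip concatenation at every level; 1 x 1
convolution + sigmoid head. The convolution kernel size defaults to
3 x 3, the conventional choice for small segmentation U-Nets.

The network, its backward pass and the Adam optimiser are implemented
directly on NumPy (im2col convolutions lowered to BLAS matrix products);
gradients are verified against central finite differences in the test
suite. He-normal initialisation from a seeded generator makes builds and
training runs bit-reproducible.

## Training

* Loss: binary cross-entropy + batch-global soft Dice (the Dice term
  keeps gradients well-scaled for the very sparse implant masks). Both
  pure variants are available.
* Adam, learning rate 1e-3, batch 32, with a x0.5 step decay at 60 % and
  85 % of the epoch budget.
* Split: 80/20, case-level by default so no slices of one volume leak
  across the train/validation boundary (a slice-level split is available
  to mirror pipelines that shuffle slices globally).
* The epoch with the best validation loss defines the retained weights.
* Augmentation: featurewise centering and unit-std scaling are fitted on
  the training slices; geometric augmentation (rotation up to ±90°,
  flips, shifts, zoom, applied identically to image and mask with the
  mask re-binarised, reflection padding) is implemented and tested but
  disabled in the reference benchmark — phantom cohorts, like
  orientation-standardized clinical scans, have a fixed anatomical
  orientation, and rotation augmentation only slows convergence there.
  An augmentation multiplier is configurable; no fixed augmented-image
  total is asserted anywhere.

## Cascade

Stage 2's input is by default the voxel-wise product of the normalised
intensity and the stage-1 bone mask (`masked_intensity`): it enforces
the cascade while preserving the texture the implant model needs. The
most literal alternative (`mask_only`, feeding the binary mask itself)
is available. The full masked volume is fed to stage 2 — no cropping to
the stage-1 bounding box — and the binarisation threshold is the sigmoid
midpoint 0.5. Prediction runs along the stacking axis (axis 2) by
default; mean or majority-vote fusion over the three axes is an opt-in
ensemble. An optional largest-connected-component filter exists but is
off by default.

## Evaluation metrics

Twelve quantities per (ground truth A, prediction B) pair: Dice,
Jaccard, precision, recall, FPR, FNR, volumetric similarity, Hausdorff
distance, MSD, StdSD, HD95 and volume error rate. Conventions that
needed fixing:

* **VS** is implemented as the volumetric dissimilarity
  |FN − FP| / (2·TP + FP + FN) — 0 for identical volumes — matching its
  verbal definition and the magnitude of published values; the commonly
  printed shorthand "VS = |A ∩ B|" is inconsistent with both.
* **MSD** follows the squared form (1/N) Σ d²; because the name is
  ambiguous in the literature, the conventional mean absolute surface
  distance is also reported (`masd`).
* Boundaries are foreground voxels with an in-grid face-adjacent
  (6-connected) background neighbour; distances are Euclidean between
  boundary voxel centres, spacing-aware in mm by default (a voxel-unit
  mode exists because published distance units are often unstated).
* HD95 is the 95th linear-interpolation percentile of the symmetric
  distance multiset.
* Degenerate cases are flagged, never silently zeroed: Dice/Jaccard of
  two empty masks are 1.0 with a warning; ratio metrics with zero
  denominators and surface metrics of empty (or boundary-less) masks are
  NaN with a flag.

Every metric is cross-checked in the tests against independently coded
brute-force oracles (set counting, O(n·m) all-pairs distance matrices),
including exhaustive enumeration of all 256 x 256 mask pairs on a
2 x 2 x 2 grid.

## Mesh export

Masks become surface meshes via marching cubes at iso 0.5 after padding
by one background voxel layer, which guarantees watertight surfaces even
when the mask touches the grid boundary; vertices are scaled into mm.
Export is binary STL. At the single-voxel limit marching cubes produces
the face-midpoint octahedron (volume = 1/6 voxel); for blocks the
enclosed volume converges to voxel count x voxel volume, which the tests
check at sizes 5, 10 and 20.

## Reference benchmark protocol

The reference evaluation trains each stage on a seeded cohort of 30
phantoms (24 train — internally split 19/5 train/validation at case
level — and 6 held-out test cases) at 79 x 112 x 135, noise SD 40 HU.
Stage 2 is conditioned on the *ground-truth* bone masks, isolating its
quality from stage-1 errors; the fully cascaded path is exercised
separately. Problem sizes for a single-CPU desk run: training slices are
taken along the prediction axis only, subsampled to every 5th slice
(adjacent 0.3 mm slices are nearly duplicates), and each stage trains
for 32 epochs. `scripts/acceptance.py` reruns this protocol from
scratch on one seed and reports the stage-1 mean volume error rate and
the stage-2 mean Dice over the 6 held-out cases.

### Resolution ceiling of the slice pathway

The 24 x 24 network grid bounds what any model can achieve after
restoration to the native grid: pushing the *ground-truth* masks through
the pathway (nearest-neighbour downsample to 24 x 24, bilinear upsample,
threshold 0.5) yields Dice ≈ 0.93 for the bone region and ≈ 0.90 for the
implant cylinder at 79 x 112 x 135. Trained models can slightly beat the
hard-mask round-trip because their soft probability maps carry sub-pixel
boundary information, but measured stage-2 Dice (~0.81 under the
reference protocol) should be read against this ceiling: the implant
cylinder spans only ~1.5–2 pixels of radius at the network grid.
The same quantization floors the stage-1 volume error rate at roughly
10–15 %: the bone block's boundary moves in steps of 3.3 / 4.7 native
voxels at the 24 x 24 grid, so per-case volume errors of that order
persist even at Dice ≈ 0.87. Clinical pipelines of this type reach
higher stage-2 scores on manually cropped ROI volumes, where the target
occupies a far larger fraction of each slice than it does here.

## Known limitations

* The phantom is geometric, not anatomical; absolute metric values do
  not transfer to clinical data.
* Training the NumPy network is one to two orders of magnitude slower
  than a compiled deep-learning framework; the benchmark protocol's
  slice subsampling and epoch budget reflect that.
* Stage 2 sees the full masked volume; slices below the implant but
  inside the bone region are ambiguous from a single axial slice, which
  costs a few percent of Dice (choosing a sagittal/coronal prediction
  axis removes the ambiguity and is configurable).
* No DICOM ingestion, no NIfTI-2, no oblique-affine resampling, no mesh
  smoothing/decimation.
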