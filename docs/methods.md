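# Methods

## Model

CMM-Net is a four-level U-shaped fully convolutional network for binary
semantic segmentation.  The encoder holds two 3×3 convolutions per level
(eight in total) and three 2×2 max poolings; the decoder holds three
bilinear 2× upsamplings, two 3×3 convolutions per stage plus a 3×3
classification head (seven in total), and a pixelwise softmax.  Every 3×3
convolution carries a bias and is followed by batch normalization and ReLU.
A pyramid pooling module (PPM) follows each of the first three encoder
levels; its concatenated output feeds both the next encoder level (through
the pooling) and the skip connection into the decoder, so multi-scale
global context is fused at every resolution rather than only at the
encoder top.  Skip connections are plain channel concatenations.

Encoder channel widths are [32, 96, 256, 512]; the decoder mirrors the
first three ([256, 96, 32]).  These widths were fixed by calibrating the
exact trainable-parameter count against the published values for two
independent configurations (10,246,562 at PPM bottleneck 64 and 13,221,794
at bottleneck 128); the solution is unique over a fine width grid and also
places the plain U-Net baseline at 7,271,330 ≈ 7.3 M parameters.  The same
calibration forces the PPM bottleneck 1×1 convolutions to be bias-free
(their batch-norm shift absorbs any bias), while all 3×3 convolutions keep
their biases.

### Dilated convolutions

All 3×3 convolutions are dilated: rates [6, 5, 4, 3] over encoder levels
(shallow → deep) and [4, 5, 6] over decoder stages (deep → shallow), so
larger feature maps receive larger receptive fields.  Zero padding of
r·(k−1)/2 preserves the spatial size at every rate.  With rates stacked in
doubling progression the receptive-field side follows 2^(r+1) − 1.  The
`building_blocks.dilated_convolve` primitive is true-convolution oriented
(an impulse returns the kernel spread with r − 1 zeros between taps); the
trainable layers use the conventional cross-correlation orientation — the
two differ only by a kernel flip, which is immaterial for learned weights.
Dilation changes no parameter count, so the thin-target (vessel) variant
with all rates 1 is parameter-identical to the dilated one.

### Pyramid pooling

Each PPM pools to four output sizes with adaptive average pooling
(bin i spans input rows [⌊i·H/s⌋, ⌈(i+1)·H/s⌉)); size 1 is exactly global
average pooling.  Defaults per dataset maximum scale m are {m, ⌊m/3⌋, 4, 1}
(48 → [48, 16, 4, 1]); small m where these collide fall back to octave
spacing {m, m/2, m/4, 1}.  Upsampling back to the feature-map size is
bilinear with the half-pixel-center (align_corners=False) convention,
implemented — like the pooling — as a separable linear map whose adjoint
gives the exact backward pass (verified against `scipy.ndimage.zoom` in
grid mode).  When a configured pooled size exceeds a level's feature-map
side (the 64-scale dermoscopy pyramid at the third level, side 48), the
builder clamps the size to that side and keeps the four sizes distinct;
the standalone functional PPM instead raises, since there the caller chose
the sizes explicitly.  Parameter counts are unaffected by pooled sizes in
either case.

## Training

Soft dice loss L = 1 − (2·Σ(SM·GT) + ε)/(ΣSM + ΣGT + ε), ε = 10⁻⁶,
averaged per sample over the batch.  The denominator uses the sum |SM|+|GT|
(the set-union notation sometimes seen for this loss is read as cardinality
shorthand): only the sum form keeps L in [0, 1] and makes L + DSC = 1 on
binarized predictions, which the tests assert.  Optimization is Adam
(β = 0.9/0.999) with the learning rate decaying per-epoch exponentially
from 10⁻⁴ to 10⁻⁵ over the scheduled epochs (100 epochs, batch 20 for the
2-D photographic tasks; 30 epochs, batch 5 for MR slices).  A smooth decay
was chosen over discrete steps because only the endpoints and the factor of
10 are pinned; the schedule exposes `learning_rate(epoch)` so a stepped
variant is a one-line subclass.  Data splits follow double cross-validation
roles: train fits weights, validation selects the best epoch (lowest
validation dice loss), test is only reported.  Training is bit-reproducible
given data, schedule, and seed; all randomness flows through
`numpy.random.Generator(PCG64)`.

Non-finite losses abort with a diagnostic rather than continuing silently;
empty datasets are rejected.

## Preprocessing pipelines

* **Dermoscopy** — bilinear rescale to 192×256 regardless of input size;
  masks resized identically and re-binarized at 0.5; [0, 1] range.
* **Fundus** — crop to the field-of-view bounding box, CLAHE per channel,
  [0, 1] normalization, then 128×128 patches (stride 64 for training,
  abutting 128 for testing).  Restitching averages overlaps and is the
  exact inverse for non-overlapping grids; scoring is at restitched
  image level restricted to FOV pixels.  CLAHE uses
  `skimage.exposure.equalize_adapthist` with an 8×8 tile grid and
  normalized clip limit 0.02 (skimage's convention; the classical
  "clip limit 2.0" parameterization belongs to a different library's
  scale).  Constant images bypass CLAHE unchanged.
* **MR volumes** — in-plane center crop 240 → 192 (configurable), channels
  stacked as (T2, FLAIR, T1Gd), per-volume per-modality min-max
  normalization.  Training uses only slices containing labels; evaluation
  passes all slices and scores the re-stacked volume as whole tumor
  (labels > 0).
* Patch windows are 0-based, (row, col), half-open; when a stride does not
  tile exactly, the final row/column of windows is anchored to the image
  edge, so coverage is total for stride ≤ patch size.

## Augmentation and inversion recovery

The eight-fold augmentation family is the dihedral group D4 (4 rotations ×
optional horizontal flip), identity first; each element's inverse is in the
group and round trips are bit-exact, so the same family serves training
augmentation and test-time recovery.  Color-space variants for dermoscopy
(LAB rescaled to [0, 1]; SV stacked as (S, V, V) to keep 3 input channels
without inventing information) are additional training samples, not fused
channels.

IR binarizes each augmented view's foreground probability at 0.5
(configurable) **before** merging, since logical operators need binary
maps; geometric views merge with OR first, then color spaces with AND.
OR can only grow the foreground, which raises sensitivity at some cost in
specificity; the mode is therefore an evaluation-time flag (`off`,
`or_only`, `or_and_colorspaces`) — on fragmented targets such as gliomas
it can reduce performance, and `off` is the default.

## Metrics

SEN, SPE, ACC, DSC, JAC, MCC from exact pixel counts (optionally within a
region of interest), reported as percentages.  Degenerate denominators
(e.g. no positives in the ground truth) return 0 with a RuntimeWarning.
ROC/PR curves and AUC delegate to scikit-learn; tests cross-check the AUC
against an exhaustive pairwise-ranking (Mann-Whitney) oracle.  Aggregation
is a weighted mean over test items (weights = sample sizes) and also emits
the per-item distributions for boxplots.

## Phantoms

The generators emulate the geometry and contrast structure of the three
tasks, not their physics:

* **lesion** — polar-perturbed ellipse (Fourier-series radius noise),
  darker than the skin-like background, smoothed boundary, low-frequency
  illumination, pixel noise, and (mostly in the `hard` setting) dark
  hair-like strokes;
* **vessel** — recursively branching tree of 1–4 px strokes drawn at
  integer centers so it is one 8-connected component, confined to a
  circular FOV on a textured orange background;
* **tumor_volume** — four correlated pseudo-modalities sharing a smooth
  anatomy field, with a bright perturbed ellipsoid confined to a contiguous
  slab of slices; labels mark exactly the tumor voxels.

Masks are exact by construction and generation is bit-deterministic per
seed.  The phantoms lack real-data nuisances — calibration drift, annotator
disagreement, pathology diversity, MR bias fields — so passing the
end-to-end tests demonstrates that the implementation learns and segments
correctly, not that it would reach benchmark accuracy on clinical data.

## Desk-scale experiment sizes

The end-to-end test trains the reduced-width configuration (widths
[8, 16, 32, 64], bottleneck 8, 64×64 inputs, ~173 k parameters) on 50 easy
lesion phantoms for 15 epochs at batch 5 with initial learning rate 10⁻³
(the larger rate suits the much smaller model), and requires held-out mean
DSC ≥ 0.85; typical runs reach 0.92–0.94 across seeds in about a minute on
one CPU.  The acceptance script's impulse cross-check uses a 33×33 image,
comfortably larger than the 7×7 footprint it measures.

## Known limitations

* CPU-only and unvectorized across samples beyond the batch dimension;
  full-size benchmark training is out of scope by design.
* Binary segmentation only (softmax over 2 classes); multi-class heads
  would need a generalized dice loss.
* BN running statistics use a fixed momentum of 0.1; very short runs eval
  with partially warmed statistics.
* The published patch counts for the fundus benchmark depend on unpublished
  FOV crop dimensions and are not reproduced; the patch grid law itself is
  tested instead.
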