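# Methods

## Problem and model

The package estimates the 3D shape of a single lumbar vertebra (L1–L5)
as a binary/probabilistic occupancy grid, from a sparse set of 4 or 8
calibrated 2D radiographs cropped to that vertebra. The approach is a
learnt multi-view stereo machine that consumes the imaging geometry
explicitly:

1. **Encoder.** Each localized radiograph (resized to 224×224, min–max
   normalized to [0, 1]) passes through a truncated 2D UNet — contracting
   channels (1)→32→64→128→256 with 3×3 convolutions and 2× max pooling,
   expanding path with skip concatenations truncated one level above the
   input resolution, and a final 1×1 projection — yielding 32 feature
   maps of 112×112 (half the input resolution).
2. **Back-projection.** Every voxel center of a world-embedded cubic
   grid (default 128³) is projected into each view with the adjusted
   projection matrix P̂ (rescaled by 0.5 for the half-resolution feature
   space); the voxel receives the bilinear interpolation of the feature
   map at that continuous pixel. Out-of-frame or behind-camera voxels
   receive zeros. The operation is linear in the feature map and hence
   differentiable end to end.
3. **Fusion.** Per-view feature grids are fused by an elementwise
   average; out-of-frustum voxels contribute zeros (a masked mean over
   the views that actually see each voxel is available behind a flag).
   Averaging is commutative, so reconstructions are invariant to view
   order; the accumulation runs in float64 and is rounded once to
   float32, making the invariance bit-exact in practice.
4. **Refiner.** A 3D UNet (channels 16→32→64→128→256, skip connections,
   final 1×1×1 projection and sigmoid) maps the fused grid to per-voxel
   occupancy probabilities; binarization uses threshold 0.5.

### Projection geometry

A calibrated view is P = K·R·[I | −t] with focal length in pixels,
principal point at the image center, 0-based pixels with centers on
integer coordinates. Cropping to a vertebral bounding box with corner
(tx, ty) gives P̂ = Q·P where Q is the unit upper-triangular shift; a
resize by factor s composes the exact affine u′ = (u + 0.5)·s − 0.5.
The world frame is right-handed millimetres, patient supine, +z toward
the head.

### Tensor backend

The network and its training run on a purpose-built reverse-mode
automatic-differentiation layer over numpy (`spinerecon.autodiff`):
3×3(×3) "same" convolutions implemented as sums of shifted
channel-GEMMs, 2× max pooling with argmax routing, nearest-neighbour
upsampling, bilinear gathering with scatter-add adjoints, and a
numerically stable BCE on logits. All gradients are validated against
central finite differences in the test suite. Tensors are float32.

## Data

### DRR simulator

A radiograph pixel is the attenuation line integral I(p) = ∫A(L(p, s)) ds
along the ray from the X-ray source through pixel p. Implementation:
fixed-step ray marching (default 0.5 mm; 2 mm at desk scale), AABB slab
clipping for entry/exit, trilinear interpolation inside the volume, zero
outside. The raw integral is kept (an exponential-transmission display
transform is a plain `exp(−I)` away and not needed for training since
images are min–max normalized). Convergence: halving the step changes
an analytic ball's central chord integral by <0.5%.

### View protocol

20 views per patient in four C-arm-reachable categories: AP (strict plus
±15° sagittal tilt), lateral (two strict, one per side, plus ±20° coronal
tilt), oblique (±20° and ±35° orbital separation from AP), and nine
miscellaneous views deviating in two planes (both angles uniform in
±[10°, 35°]). Views are parameterized by (orbital, tilt): orbital
rotation about the patient's long axis, cranio-caudal tilt about the
in-plane horizontal — for AP views the tilt lies in the sagittal plane,
for lateral views in the coronal plane. Focal lengths are drawn per view
from {850, 900, 1000} pixels (different C-arm designs). The source is
placed so the target sits at 0.7× focal-length depth, increased when
needed so the volume's bounding sphere fits the frame with 5% margin.
Network inputs take one view per category (4-view) or those four plus
four drawn from the whole pool (8-view).

### Phantoms

The synthetic stand-in for a spine CT cohort: five stacked vertebra-like
bodies (elliptic-cylinder body with a 2-voxel denser cortical shell, a
posterior ring with an open spinal canal, one spinous and two transverse
processes) inside a soft-tissue torso cylinder. Attenuations default to
0.02 mm⁻¹ (soft tissue, ≈ water at ~60 keV) and 0.06 mm⁻¹ (cortical
bone), trabecular interior at 55% of cortical. Per-level geometry (body
radius 14–19 mm, height 20–26 mm, canal radius 4.5–6.5 mm, process
length 16–26 mm) is drawn per seed; all bone voxels of a level share one
label and form a single 6-connected component. Full-scale default is
144×144×224 voxels at 0.9 mm (satisfying the cohort inclusion criteria:
sub-millimetre spacing, >128 voxels per axis, all five levels); the desk
preset is 64×64×96 at 2 mm.

What the phantoms do *not* emulate: anatomical shape statistics,
cortical/trabecular texture, pathology, scatter/beam-hardening/noise in
the radiographs, and neighbouring anatomy beyond the five levels. Tests
passing on phantoms demonstrate the pipeline's geometric and learning
machinery, not clinical-grade accuracy on real CTs.

### Elastic augmentation

Displacement fields interpolated with cubic splines from a 6×6×6 control
grid whose control points are displaced per axis by uniform [0, 18]
voxels; values warp trilinearly, labels nearest-neighbour, the same
field for both. Applied to the 3D volume before rendering, and (in the
replication recipe) only for the binary-segmented variant, doubling that
dataset.

### Dataset building

Full-size DRRs → per-level 2D masks (projected voxel centers, raster
closing, hole filling) and tight bounding boxes → square crops with 10%
margin (keeping neighbouring anatomy context), resized with the exact
affine to the input size and normalized → P̂ via crop shift + resize
scaling. Segmented variants: grayscale = image ⊙ mask, binary =
(grayscale > 0). Ground-truth occupancy: nearest-neighbour lookup of the
label volume at grid voxel centers, on a cube centered on the level's 3D
bounding box with side 1.5× its largest extent (the grid's physical
embedding is a package choice). Patient-level split: test =
round(10%·N), validation = round(20%·N), train = remainder, after a
seeded shuffle.

## Training

Voxelwise binary cross-entropy on the occupancy logits (the canonical
loss for sigmoid occupancy; the refiner's sigmoid and the loss are fused
for numerical stability), Adam at learning rate 1e-4, effective batch
size 16 via gradient accumulation (per-step batch 1), early stopping on
validation loss with patience 5, up to 40 epochs — the full-scale
recipe. Accumulating k single-sample gradients scaled by 1/k is
numerically identical to one batch-of-k step, which the suite asserts.

**Desk preset** (everything a CPU can do in minutes): 64² crops, 32³
grids, encoder channels (16,32,64), refiner (8,16,32) — still 32 feature
maps at half resolution — 44 phantoms (220 vertebrae; 200 train / 10
validation / 20 test after the patient-level split), 4 epochs. Three
recipe adjustments at this scale, chosen once: learning rate 1e-3 with
accumulation 4 (the slim model sees only a few hundred updates, so the
full-scale 1e-4/batch-16 recipe cannot move it measurably); the output
bias initialized to −2, the logit of the sparse occupancy prior
(~5–10%), which removes the long initial phase of pushing the
background down; and a positive-class weight of 3 in the voxelwise BCE
— with ~3–7% occupied voxels, the unweighted loss leaves short-budget
models under-confident (probabilities compressed toward the prior, so
the canonical 0.5 binarization threshold under-segments), and the
weight is the standard counterbalance. Problem sizes throughout
(phantom resolution, 1500–2000 surface
sample points, render step 2 mm) are the package's desk-scale choices.

## Evaluation

* **F1 / IoU** on binary grids (2TP/(2TP+FP+FN), TP/(TP+FP+FN)); two
  empty grids score 1 by convention.
* **Surface score S(d)**: meshes extracted at iso-level 0.5 (marching
  cubes on a one-voxel zero pad, vertices mapped to world mm), 10,000
  area-uniform points sampled per mesh (seeded; 1500–2000 at desk
  scale), precision(d) = fraction of prediction points with nearest
  ground-truth point strictly closer than d, recall mirrored, S =
  harmonic mean; d = 1% of the reconstruction volume's side length.
  Monte-Carlo error of S at 10⁴ points is below ~0.01.
* **HD95 / ASD**: 95th percentile and mean of the pooled bidirectional
  nearest-neighbour distances (symmetric; the directionality convention
  is a package choice), in mm.
* **Calibration sensitivity**: the focal length parameter of AP or
  lateral views is perturbed by up to 50 mm (images unchanged — a pure
  calibration error; P̂ is recomposed from its recovered pixel-transform
  and perturbed intrinsics) and metrics recomputed per delta.

Identical prediction/target grids score S = 1 and HD95 = ASD = 0 exactly
because both meshes are sampled with the same seed.

## Numerical choices and degenerate inputs

* Binarization threshold 0.5; sigmoid outputs clipped to (1e-7, 1−1e-7)
  where strict openness is required.
* Projection with |w| < 1e-12 raises a point-at-infinity error; rotation
  orthonormality is enforced to 1e-9.
* Empty prediction or target: overlap scores fall back to their set
  definitions; surface metrics report 0 (score) and the grid side
  length (distances) rather than failing.
* Strict inequality (< d) in surface precision/recall, as defined.
* All randomness flows through seeded `numpy.random.default_rng`
  generators; runs are bit-reproducible single-process.

## Known limitations

* The desk-scale study demonstrates the pipeline end to end but its
  absolute scores are not comparable to a full-scale multi-GPU training
  on real CT cohorts (data realism, resolution and training budget all
  differ by orders of magnitude).
* Ray marching is fixed-step (no adaptive quadrature); photometric
  effects (scatter, beam hardening, detector response) are out of scope.
* The 8-view configuration is supported but the shipped study uses the
  4-view baseline.
* C-arm calibration and vertebra localization on real radiographs are
  consumed as given (bounding boxes and P-matrices are inputs).
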