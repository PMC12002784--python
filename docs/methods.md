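# Methods

## Overview

`trusseg` implements an automated pipeline for 3D segmentation of the
prostate and its zones — transition zone (TZ) and peripheral zone (PZ) —
from 3D transrectal ultrasound: grayscale B-mode volumes and 4D
contrast-enhanced ultrasound (CEUS) acquisitions collapsed to a 3D
mean-intensity volume.  The pipeline has four stages:

1. **Radial resampling.**  The volume is resampled into 2D planes that each
   contain the probe's sweep axis, at a fixed angular step (default 10°,
   hence 18 planes covering the full cylinder: each plane covers its angle
   with positive in-plane radius *s* and the opposite angle with negative
   *s*).  Radial views present the gland comparably in every plane, which
   makes 2D learning far more sample-efficient than axial slicing.  Each
   plane is accompanied by two parallel context planes offset ±4 mm along
   the plane normal.
2. **2D segmentation.**  A small convolutional encoder–decoder with skip
   connections takes the three planes as channels and emits two sigmoid
   channels: prostate probability and zone discrimination (TZ probability
   over the plane).  One network is trained per modality.
3. **Cylindrical reconstruction.**  Per-voxel cylindrical coordinates
   (r, θ, z) select the two half-planes bracketing θ; their probabilities
   are sampled bilinearly at (±r, z), blended linearly in angle, and
   thresholded at 0.5.  Interpolating in probability space before
   thresholding gives smoother boundaries than interpolating binary masks
   (this is why the worst-case surface distance typically *improves* on
   reconstruction).
4. **Zone composition.**  TZ = raw-TZ ∩ prostate and PZ = prostate ∖ TZ, so
   the zones exactly partition the gland by construction.  (A "union of the
   prostate with the complement of the TZ" would cover all non-TZ tissue
   including background; the intersection/difference form is the only
   reading that yields a peripheral zone.)

## Coordinate conventions

Volumes are axis-aligned voxel grids in (x, y, z) order; world position of
voxel (i, j, k) is `origin + (i, j, k) * spacing` (node-centred, 0-based,
mm).  Files with non-identity direction cosines are resampled to an
axis-aligned grid on read.  The cylinder axis is the volume's z axis through
a configurable `axis_point` (default: the xy-centre).  The probe sits
posterior, at +y; *anterior* is −y; the gland *base* is +z.  A plane-grid
point (s, z) of plane k maps to world
`(axis_x + s·cos θ_k, axis_y + s·sin θ_k, z)` with θ_k = k · Δθ, so the
s = 0 column is the axis for every plane.

## Sampling and interpolation choices

* Intensities are sampled trilinearly; binary masks are sampled trilinearly
  on their indicator and thresholded at 0.5 (deterministic, smooth).
* Out-of-volume samples are edge-replicated, avoiding spurious dark rims at
  plane borders.
* The plane pixel grid runs over s ∈ [−half-width, +half-width] and the full
  z extent at `in_plane_spacing` (0.5 mm default for analysis-resolution
  work; the phantom study uses 1.5 mm to match its 1.5 mm voxels).
* "Two additional parallel planes, 4 mm between them" is read as each
  context plane lying 4 mm from the central plane (±4 mm); the alternative
  reading (±2 mm) is available through `context_offset`.
* Reconstruction voxels with r beyond the sampled half-width are background;
  an optional morphological closing is off by default.

## Network and training

The encoder–decoder has `depth` levels of two 3×3 convolutions + ReLU with
channel widths `base_width · 2^i`, 2×2 max pooling, a bottleneck, nearest-
neighbour upsampling with skip concatenation, and a 1×1 linear head with
sigmoid outputs.  It is implemented directly on numpy arrays with explicit
forward/backward passes (float32, Adam), sized for single-CPU training.
The default configuration is depth 3, base width 8 (~122 k parameters) on
~64×64 radial planes — small enough that the complete phantom study trains
in minutes on one CPU while still saturating the phantom task; larger
configurations (up to tens of millions of parameters) are reachable through
`ModelConfig` but are not defaults.  Inputs are standardised per plane and
channel and reflect-padded to a multiple of 2^depth; outputs are cropped
back.

Training minimises per-channel soft-Dice + binary cross-entropy, which
directly optimises the reported metric family.  The zone channel is
supervised with the TZ plane mask over the whole plane; PZ is derived
downstream.  Cross-validation is fivefold by default: a seeded permutation
split into near-equal folds, every case validating exactly once.  Early
stopping: up to 60 epochs ("iterations" at epoch granularity — validation
is computed once per epoch, matching the patience phrasing), halting once
the mean validation Dice has not strictly improved for 10 consecutive
epochs; best-epoch weights are retained.  One master seed drives fold
assignment, weight initialisation and data order.  Probability outputs are
binarised at 0.5.

## Evaluation metrics

Per case and structure, in 3D (volume masks) and 2D (per radial plane,
averaged over the fan):

* **DSC** = 2|A∩B|/(|A|+|B|) and **IoU** = |A∩B|/|A∪B| (identity
  IoU = DSC/(2−DSC)); a both-empty pair scores 1, a one-empty pair 0.
* **RVD** = (V_auto − V_ref)/V_ref × 100 (positive = over-segmentation).
* **MSD/HD**: surfaces are centres of foreground voxels with ≥1
  six-connected background neighbour (volume border counts as background),
  in world mm.  MSD is the symmetric average of the two directed mean
  nearest-neighbour distances; HD is the exact symmetric maximum
  (worst-case agreement, not a percentile).
* Aggregation: mean with a 95% Student-t confidence interval over cases
  (undefined, reported as NaN, below two cases).  2D ground truth is the 3D
  reference resliced with the same radial geometry.

Volume agreement: mask volume (voxel count × voxel volume), the triaxial
ellipsoid formula V = (π/6)·L·W·H (diameters in cm), PSA density
(PSA/volume), Bland-Altman bias with 1.96·SD limits of agreement on
differences *reference-style minus automated* (so a larger reference volume
gives positive bias), and R² as the squared Pearson correlation (identical
to simple-regression R²).  Gland-size strata: small < 40 cm³,
medium 40–70 cm³ (boundaries inclusive), large > 70 cm³.

## Synthetic phantom cohort

No public 3D TRUS cohort with zonal ground truth exists, so the package
ships a phantom generator that emulates the geometry and first-order
appearance of the clinical data:

* **Shape.**  The gland is star-convex: an ellipsoid radius function
  modulated by seeded low-order spherical harmonics (orders 2–3, amplitude
  ≤ 0.3 relative).  Star-convexity guarantees every radial plane sees a
  single well-defined cross-section.  The TZ is an inner star-convex region
  anchored toward the anterior-basal gland, scaled by bisection on the
  rasterized volume ratio until TZ/prostate is within ±5% of the requested
  fraction (default target drawn from 0.35–0.55 per case); PZ is the exact
  complement within the gland.
* **B-mode.**  Hypoechoic interior (0.32) against brighter background
  (0.55), a 3 mm echogenic capsule rim (0.85), a mild TZ level offset
  (+0.07), multiplicative unit-mean gamma speckle (SD 0.35) and 0.8 mm
  Gaussian blur.  The boundary is most distinct in this modality.
* **CEUS.**  No rim; PZ enhancement 0.55 vs background 0.18 with the
  anterior TZ hypo-enhanced (−0.30) — zones are easiest to tell apart
  here — an anterior→posterior multiplicative suppression gradient
  (strength 0.4; contrast signal is weakest far from the posterior probe,
  so the anterior boundary is least distinct), additive noise (SD 0.04),
  1.2 mm blur, and slab-wise lateral jitter (SD 0.5 mm per 12 mm slab)
  emulating patient motion over the ~2-minute acquisition.
* **Cohort.**  Cases span the three clinical volume strata with
  largest-remainder rounding of the requested proportions (51 cases at
  equal proportions → 17/17/17).  Per-case target volumes are drawn from
  bands kept clear of the 40/70 cm³ cut-offs so rasterization cannot move a
  case across a stratum boundary.  Default grids are 64³ at 1.5 mm
  (96 mm field of view).  Generation is a pure function of
  (n, proportions, template, seed).

What the phantoms do **not** model: acoustic wave propagation, shadowing,
refraction, anisotropic speckle, microbubble kinetics, pathology (tumours,
calcifications, median lobes), probe deformation of the gland, and
inter-observer ground-truth variability.  Passing the phantom study
therefore demonstrates that the *pipeline machinery* — geometry, learning,
reconstruction, metrics — is correct and self-consistent at realistic
gland scales; it does not certify clinical accuracy on patient images.

## Desk-scale phantom study

`trusseg.experiments.run_phantom_study` trains the default B-mode network
on 40 phantoms and evaluates the full pipeline on 10 held-out phantoms
(split by a seeded permutation so the held-out set mixes strata).  Training
runs up to 12 epochs with patience 10 — validation Dice plateaus around
epoch 8–10 on this cohort — with batch size 8 and Adam at 3·10⁻³.  Reported
outputs: 3D and 2D DSC/IoU/RVD/MSD/HD for the prostate boundary, zonal DSC
(mean of TZ and PZ), and volume agreement between the predicted mask volume
and the ellipsoid-formula volume computed from the phantom's true axis
diameters (the ellipsoid formula ignores the surface perturbation, so it
plays the role of the smooth reference estimate).  Zonal accuracy trails
whole-gland accuracy, reproducing the qualitative ordering seen clinically.

## Numerical and degenerate-input conventions

* Both-empty mask pairs: DSC = IoU = 1; one-empty: 0 with surface metrics
  undefined (error raised / excluded from plane averages).
* RVD requires a non-empty reference.
* Angular interval must divide 180°; plane indices outside [0, n) raise.
* Meshing smooths the mask indicator (σ = 0.6 voxel) before marching cubes
  so surface area is not inflated by the voxel staircase, and pads the
  volume so border-touching masks close; empty masks raise.
* Determinism: every stochastic component (phantoms, fold splits, weight
  init, batch order) derives from explicit integer seeds; repeated runs are
  bit-identical.

## Known limitations

* The cylindrical reconstruction cannot represent structures invisible in
  every radial plane (off-axis details thinner than the angular step), and
  accuracy degrades for glands centred far from the probe axis.
* The zone channel is a TZ-probability map; alternative encodings (boundary
  maps, in-gland discriminators) were not explored.
* Training-time options are minimal by design (no augmentation, no
  learning-rate schedule); the phantom task does not need them, real data
  likely would.
* The evaluation reslices 3D ground truth for 2D metrics; independently
  drawn 2D annotations would behave differently near the axis where planes
  oversample.
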