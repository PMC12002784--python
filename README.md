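# trusseg

Automated 3D segmentation of the prostate and its zones — transition zone
(TZ) and peripheral zone (PZ) — from 3D transrectal ultrasound: grayscale
B-mode volumes and contrast-enhanced ultrasound (CEUS) acquisitions
collapsed to 3D mean-intensity volumes.  Built for researchers working on
ultrasound-based prostate cancer diagnostics who need reproducible gland
and zone masks, volumes and PSA density without slice-by-slice manual
contouring.

## Method

The pipeline exploits the roughly cylindrical field of view of a motorized
transrectal sweep:

1. **Radial resampling** — the volume is resampled into 2D planes
   containing the probe axis at 10° steps (18 planes cover the cylinder;
   plane *k* covers angle θ_k at positive in-plane radius *s* and
   θ_k + 180° at negative *s*).  Each plane carries two parallel context
   planes at ±4 mm.
2. **2D segmentation** — a per-modality convolutional encoder–decoder
   (U-Net-style, 3 input channels, 2 sigmoid outputs: prostate probability
   and TZ discrimination) segments every plane.  Training uses fivefold
   cross-validation with early stopping (≤60 epochs, patience 10, best
   weights kept).
3. **Cylindrical reconstruction** — each output voxel (r, θ, z) blends the
   two planes bracketing θ, sampled bilinearly at (±r, z), linearly in
   angle; the blended probability is thresholded at 0.5.
4. **Zone composition** — TZ = raw-TZ ∩ prostate, PZ = prostate ∖ TZ, so
   TZ ∪ PZ = prostate and TZ ∩ PZ = ∅ exactly.

Evaluation follows the standard segmentation metric family — DSC, IoU,
RVD (%), mean surface distance (MSD, mm) and exact Hausdorff distance
(HD, mm), in 2D (per-plane mean) and 3D, aggregated as mean (95% CI) — and
volume agreement via Bland-Altman bias/limits and R² against the triaxial
ellipsoid formula V = (π/6)·L·W·H, plus PSA density (PSA/volume).

Because no public 3D TRUS cohort with zonal ground truth exists, the
package includes a synthetic phantom generator: star-convex glands
(harmonically perturbed ellipsoids) with an anterior-basal TZ, B-mode
speckle/rim appearance, CEUS zone contrast with anterior signal
suppression and motion jitter, spanning the clinical volume strata
(<40 / 40–70 / >70 cm³).  See `docs/methods.md` for the full model and its
limitations.

## Worked example

Train the B-mode network on 40 synthetic phantoms and evaluate the full
pipeline on 10 held-out phantoms:

```python
from trusseg.experiments import run_phantom_study

study = run_phantom_study(n_train=40, n_test=10, seed=1, modality="bmode")
a = study.aggregates
print(f"3D prostate DSC {a['dsc_3d_mean']:.3f}   zonal DSC {a['zonal_dsc_3d_mean']:.3f}")
print(f"3D MSD {a['msd_3d_mm_mean']:.2f} mm      HD {a['hd_3d_mm_mean']:.2f} mm")
print(f"volume bias {a['volume_bias_cm3']:+.2f} cm3   R2 {a['volume_r_squared']:.3f}")
```

With seed 1 this prints:

```
3D prostate DSC 0.983   zonal DSC 0.919
3D MSD 0.31 mm      HD 1.50 mm
volume bias +0.89 cm3   R2 1.000
```

Reading: held-out whole-gland masks overlap the exact ground truth at DSC
0.983 with sub-voxel mean boundary error; zonal masks score lower (0.919)
because zone discrimination is the harder task — the same ordering observed
in clinical evaluations.  The ellipsoid-formula volume (from the phantoms'
true axis diameters) agrees with the predicted mask volume with a small
positive bias, the direction expected when a smooth three-diameter
approximation is compared against a perturbed gland surface.

The same stages are scriptable from the shell:

```sh
trusseg simulate --n 9 --seed 7 --out cohort/
trusseg train --modality bmode --data cohort/ --folds 3 --out run/
trusseg segment --model run/fold0.npz --in cohort/phantom_000/bmode.nii.gz \
    --out pred.nii.gz --mesh gland.stl
trusseg compare-volumes --pairs pairs.csv --out agreement.csv
```

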