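"""Synthetic ultrasound phantom cohort with exact zonal ground truth.

Generates co-registered B-mode and mean-intensity CEUS volumes of a
star-convex prostate gland with an inner transition zone (TZ), plus exact
voxel masks.  The gland boundary is an ellipsoid radius function modulated by
seeded low-order spherical harmonics (star-convexity keeps the radial-plane
representation well posed).  The peripheral zone (PZ) is the gland minus the
TZ by construction, so the zone partition is exact.

Appearance model (chosen to mirror the qualitative properties of transrectal
imaging rather than acoustic physics):

* **B-mode** — hypoechoic gland interior against a brighter background, a
  bright rim band at the capsule (the boundary is most distinct in this
  modality), a mild TZ/PZ level difference, multiplicative unit-mean speckle
  and Gaussian blur.
* **CEUS (temporal mean)** — strong TZ/PZ enhancement contrast (zones are
  easiest to tell apart here), with the anterior-anchored TZ hypo-enhanced
  relative to the PZ; no capsule rim; an anterior-to-posterior multiplicative
  suppression gradient (contrast signal is attenuated far from the posterior
  probe), so the anterior gland boundary is the least distinct; additive
  noise; and optional slab-wise lateral jitter emulating patient motion over
  the ~2-minute acquisition.

Coordinate convention: the probe sits posterior (at +y); *anterior* is the
−y direction; *base* (toward the bladder) is +z.

Cohorts span three clinically used gland-size strata: small (<40 cm^3),
medium (40–70 cm^3) and large (>70 cm^3), with stratum counts assigned by
largest-remainder rounding (the default mirrors an equally distributed
cohort, e.g. 51 cases -> 17 per stratum).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.special import sph_harm_y

from .volume_agreement import stratify_by_volume
from .volume_io import SegmentationMask, Volume3D

__all__ = [
    "BModeParams",
    "CeusParams",
    "PhantomSpec",
    "PhantomCase",
    "SimulationError",
    "sample_shape",
    "render_bmode",
    "render_ceus",
    "generate_case",
    "generate_cohort",
]


class SimulationError(RuntimeError):
    """Raised when a requested phantom configuration is unreachable."""


@dataclass(frozen=True)
class BModeParams:
    """B-mode appearance levels (arbitrary intensity units in [0, 1])."""

    interior: float = 0.32
    background: float = 0.55
    rim: float = 0.85
    rim_width_mm: float = 3.0
    zone_contrast: float = 0.07  # TZ sits this much above the PZ interior level
    speckle: float = 0.35  # multiplicative speckle strength (SD of unit-mean noise)
    blur_sigma_mm: float = 0.8  # B-mode resolves finer detail than CEUS


@dataclass(frozen=True)
class CeusParams:
    """Mean-intensity CEUS appearance."""

    background: float = 0.18
    pz_level: float = 0.55
    zone_contrast: float = 0.30  # TZ sits this far below the PZ level
    suppression: float = 0.40  # anterior multiplicative suppression strength in [0, 1)
    noise: float = 0.04  # additive Gaussian noise SD
    blur_sigma_mm: float = 1.2
    motion_jitter_mm: float = 0.5  # SD of slab-wise lateral shifts
    jitter_slab_mm: float = 12.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full specification of one phantom; a (spec, seed) pair is a pure
    function of its fields — identical inputs give bit-identical outputs."""

    semi_axes: tuple[float, float, float] = (20.0, 25.0, 30.0)  # (a, b, c) mm
    perturbation_amplitude: float = 0.08  # relative radial perturbation, 0-0.3
    tz_fraction: float = 0.45  # target TZ/prostate volume ratio
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)  # mm
    bmode: BModeParams = field(default_factory=BModeParams)
    ceus: CeusParams = field(default_factory=CeusParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.perturbation_amplitude <= 0.3):
            raise ValueError("perturbation_amplitude must be in [0, 0.3]")
        if not (0.2 <= self.tz_fraction <= 0.7):
            raise ValueError("tz_fraction must be in [0.2, 0.7]")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")


@dataclass
class PhantomCase:
    """One synthetic patient: both modalities plus exact ground truth."""

    case_id: str
    bmode: Volume3D
    ceus: Volume3D
    prostate_mask: SegmentationMask
    tz_mask: SegmentationMask
    pz_mask: SegmentationMask
    true_volume: float  # cm^3, from the prostate mask
    stratum: str
    spec: PhantomSpec


def _direction_grids(spec: PhantomSpec):
    """World offsets from the gland centre and their spherical angles."""
    shape = np.array(spec.grid_shape)
    sp = np.asarray(spec.spacing)
    centre = (shape - 1) / 2.0 * sp
    ax = [np.arange(n) * s for n, s in zip(shape, sp)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    dx, dy, dz = X - centre[0], Y - centre[1], Z - centre[2]
    rho = np.sqrt(dx * dx + dy * dy + dz * dz)
    with np.errstate(invalid="ignore", divide="ignore"):
        polar = np.arccos(np.clip(np.where(rho > 0, dz / rho, 1.0), -1, 1))
    azimuth = np.arctan2(dy, dx)
    return dx, dy, dz, rho, polar, azimuth, centre


def _harmonic_field(polar, azimuth, rng, l_orders=(2, 3)) -> np.ndarray:
    """Smooth random angular field in [-1, 1] from low-order real spherical
    harmonics with seeded coefficients."""
    f = np.zeros_like(polar)
    for l in l_orders:
        for m in range(-l, l + 1):
            c = rng.normal()
            y = sph_harm_y(l, abs(m), polar, azimuth)
            f += c * (y.real if m >= 0 else y.imag)
    peak = np.abs(f).max()
    if peak > 0:
        f /= peak
    return f


def _star_convex_mask(dx, dy, dz, rho, pert, semi_axes, amplitude) -> np.ndarray:
    a, b, c = semi_axes
    # ellipsoid radius along each voxel direction: rho / r_e = |scaled offset|
    q = np.sqrt((dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2)
    return q <= (1.0 + amplitude * pert)


def sample_shape(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[SegmentationMask, SegmentationMask, SegmentationMask]:
    """Rasterize the gland, TZ and PZ masks for one phantom.

    The gland is star-convex: radius = ellipsoid radius x (1 + smooth
    low-order perturbation bounded by ``perturbation_amplitude``).  The TZ is
    an inner star-convex region anchored toward the anterior-basal gland and
    scaled (by bisection on the rasterized ratio) until the TZ/prostate
    volume ratio is within ±2% of ``tz_fraction``; a spec whose ratio cannot
    be reached raises :class:`SimulationError`.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    dx, dy, dz, rho, polar, azimuth, centre = _direction_grids(spec)
    a, b, c = spec.semi_axes

    pert = _harmonic_field(polar, azimuth, rng)
    prostate = _star_convex_mask(dx, dy, dz, rho, pert, spec.semi_axes,
                                 spec.perturbation_amplitude)
    n_prostate = int(prostate.sum())
    if n_prostate == 0:
        raise SimulationError("gland does not intersect the grid")

    # TZ: inner region offset toward anterior (-y) and base (+z)
    off = np.array([0.0, -0.12 * b, 0.15 * c])
    tdx, tdy, tdz = dx - off[0], dy - off[1], dz - off[2]
    trho = np.sqrt(tdx * tdx + tdy * tdy + tdz * tdz)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpolar = np.arccos(np.clip(np.where(trho > 0, tdz / trho, 1.0), -1, 1))
    tazim = np.arctan2(tdy, tdx)
    tpert = _harmonic_field(tpolar, tazim, rng)
    # normalized ellipsoid radius of the TZ at scale 1; mask at scale s is q <= s
    q = np.sqrt((tdx / a) ** 2 + (tdy / b) ** 2 + (tdz / c) ** 2)
    q_eff = q / (1.0 + 0.5 * spec.perturbation_amplitude * tpert)

    def ratio(s: float) -> float:
        return int(((q_eff <= s) & prostate).sum()) / n_prostate

    lo, hi = 0.05, 1.2
    if ratio(hi) < spec.tz_fraction - 0.02:
        raise SimulationError(
            f"tz_fraction {spec.tz_fraction} unreachable (max {ratio(hi):.3f})"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if ratio(mid) < spec.tz_fraction:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    s = hi
    if abs(ratio(s) - spec.tz_fraction) > 0.05 * spec.tz_fraction:
        raise SimulationError(
            f"achieved TZ fraction {ratio(s):.3f} too far from target {spec.tz_fraction}"
        )
    tz = (q_eff <= s) & prostate
    pz = prostate & ~tz

    def _mask(arr):
        return SegmentationMask(arr.astype(np.uint8), spec.spacing, (0.0, 0.0, 0.0))

    return _mask(prostate), _mask(tz), _mask(pz)


def _boundary_band(mask: np.ndarray, width_vox: int) -> np.ndarray:
    inner = ndimage.binary_erosion(mask, iterations=max(width_vox, 1), border_value=0)
    return mask & ~inner


def render_bmode(
    prostate: SegmentationMask,
    tz: SegmentationMask,
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
) -> Volume3D:
    """Render the B-mode appearance for a rasterized gland (see module
    docstring for the model).  Deterministic under the spec seed."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    p = spec.bmode
    gland = prostate.foreground()
    img = np.full(gland.shape, p.background, dtype=np.float64)
    img[gland] = p.interior
    img[tz.foreground()] = p.interior + p.zone_contrast
    rim_vox = max(int(round(p.rim_width_mm / min(spec.spacing))), 1)
    img[_boundary_band(gland, rim_vox)] = p.rim
    if p.speckle > 0:
        shape_k = 1.0 / (p.speckle**2)
        img *= rng.gamma(shape_k, 1.0 / shape_k, size=img.shape)
    if p.blur_sigma_mm > 0:
        img = ndimage.gaussian_filter(img, sigma=np.array(p.blur_sigma_mm) / np.asarray(spec.spacing))
    return Volume3D(img, spec.spacing, (0.0, 0.0, 0.0))


def _anterior_suppression(shape, spacing, strength: float) -> np.ndarray:
    """Multiplicative factor: 1 at the posterior face (+y, probe side),
    1 - strength at the anterior face (-y)."""
    ny = shape[1]
    frac_from_posterior = (ny - 1 - np.arange(ny)) / max(ny - 1, 1)
    factor = 1.0 - strength * frac_from_posterior
    return factor[None, :, None]


def render_ceus(
    prostate: SegmentationMask,
    tz: SegmentationMask,
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
) -> Volume3D:
    """Render the mean-intensity CEUS appearance (zone contrast, anterior
    suppression, motion jitter).  Deterministic under the spec seed."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    p = spec.ceus
    gland = prostate.foreground()
    img = np.full(gland.shape, p.background, dtype=np.float64)
    img[gland] = p.pz_level
    img[tz.foreground()] = p.pz_level - p.zone_contrast
    if p.suppression > 0:
        img = img * _anterior_suppression(img.shape, spec.spacing, p.suppression)
    if p.noise > 0:
        img = img + rng.normal(0.0, p.noise, size=img.shape)
    if p.blur_sigma_mm > 0:
        img = ndimage.gaussian_filter(img, sigma=np.array(p.blur_sigma_mm) / np.asarray(spec.spacing))
    if p.motion_jitter_mm > 0:
        slab = max(int(round(p.jitter_slab_mm / spec.spacing[2])), 1)
        nz = img.shape[2]
        for z0 in range(0, nz, slab):
            shift_vox = rng.normal(0.0, p.motion_jitter_mm) / spec.spacing[0]
            img[:, :, z0 : z0 + slab] = ndimage.shift(
                img[:, :, z0 : z0 + slab], (shift_vox, 0.0, 0.0),
                order=1, mode="nearest")
    return Volume3D(img, spec.spacing, (0.0, 0.0, 0.0))


def generate_case(spec: PhantomSpec, case_id: str = "case") -> PhantomCase:
    """Generate one complete phantom (shape, both modality renders, masks)."""
    prostate, tz, pz = sample_shape(spec)
    bmode = render_bmode(prostate, tz, spec)
    ceus = render_ceus(prostate, tz, spec)
    vol_cm3 = int(prostate.foreground().sum()) * prostate.voxel_volume_mm3 / 1000.0
    stratum = stratify_by_volume([vol_cm3])[0]
    return PhantomCase(
        case_id=case_id,
        bmode=bmode,
        ceus=ceus,
        prostate_mask=prostate,
        tz_mask=tz,
        pz_mask=pz,
        true_volume=vol_cm3,
        stratum=stratum,
        spec=spec,
    )


def _largest_remainder_counts(n: int, proportions) -> list[int]:
    props = np.asarray(proportions, dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("strata proportions must sum to 1")
    raw = props * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in order[:remainder]:
        counts[i] += 1
    return counts.tolist()


# Target-volume bands (cm^3) kept clear of the stratum cut-offs so that
# voxelization and surface perturbation cannot move a case across a boundary
_STRATUM_BANDS = {"small": (22.0, 38.0), "medium": (43.0, 67.0), "large": (73.0, 98.0)}


def _semi_axes_for_volume(volume_cm3: float, rng: np.random.Generator) -> tuple[float, float, float]:
    """Random mild anisotropy with (4/3)π·abc equal to the target volume."""
    ratios = rng.uniform(0.8, 1.25, size=3)
    k = (volume_cm3 * 1000.0 * 3.0 / (4.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
    a, b, c = (k * r for r in ratios)
    return float(a), float(b), float(c)


def generate_cohort(
    n: int,
    strata_proportions=(1 / 3, 1 / 3, 1 / 3),
    spec_template: PhantomSpec | None = None,
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate a cohort spanning the three volume strata.

    Stratum counts follow largest-remainder rounding of the proportions
    (n=51 with equal proportions gives 17/17/17).  Each case draws its target
    volume uniformly within its stratum band, a mildly anisotropic ellipsoid
    shape, and a TZ fraction in [0.35, 0.55]; generation is a pure function
    of ``(n, strata_proportions, spec_template, seed)``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if spec_template is None:
        spec_template = PhantomSpec()
    counts = _largest_remainder_counts(n, strata_proportions)
    grid_mm = (np.array(spec_template.grid_shape) - 1) * np.asarray(spec_template.spacing)
    max_radius_mm = grid_mm.min() / 2.0
    cases: list[PhantomCase] = []
    idx = 0
    for stratum, count in zip(("small", "medium", "large"), counts):
        lo, hi = _STRATUM_BANDS[stratum]
        for _ in range(count):
            case_rng = np.random.default_rng(np.random.SeedSequence([seed, idx]))
            target = case_rng.uniform(lo, hi)
            axes = _semi_axes_for_volume(target, case_rng)
            if max(axes) * (1 + spec_template.perturbation_amplitude) >= max_radius_mm:
                raise SimulationError(
                    f"target volume {target:.1f} cm^3 does not fit the "
                    f"{spec_template.grid_shape} grid"
                )
            case_seed = int(case_rng.integers(0, 2**31 - 1))
            spec = replace(
                spec_template,
                semi_axes=axes,
                tz_fraction=float(case_rng.uniform(0.35, 0.55)),
                seed=case_seed,
            )
            case = generate_case(spec, case_id=f"phantom_{idx:03d}")
            if case.stratum != stratum:
                raise SimulationError(
                    f"case {idx} landed in stratum {case.stratum!r}, wanted {stratum!r}"
                )
            cases.append(case)
            idx += 1
    return cases
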