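"""Cylindrical 3D reconstruction of per-plane 2D segmentations.

The per-plane probability maps live on a fan of radial planes; a 3D mask is
recovered by *cylindrical interpolation*: each output voxel is expressed in
cylindrical coordinates ``(r, theta, z)`` about the probe axis, the two
half-planes angularly bracketing ``theta`` are sampled bilinearly at
``(±r, z)`` (plane ``k`` covers angle ``theta_k`` at positive in-plane radius
and ``theta_k + 180°`` at negative radius), the two samples are blended
linearly in angle, and the blended probability is thresholded.

Interpolating in probability space *before* thresholding yields smoother
reconstructed boundaries than interpolating binary masks.  Voxels outside
the sampled cylinder (``r`` beyond the plane half-width) are background.

Zone composition: the raw transition-zone channel is restricted to the
reconstructed gland (TZ = raw-TZ ∩ prostate) and the peripheral zone is the
set difference PZ = prostate ∖ TZ, so the two zones exactly partition the
gland.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .radial_geometry import RadialGeometry
from .volume_io import Mesh, SegmentationMask, Volume3D

__all__ = [
    "ReconstructionConfig",
    "reconstruct_mask",
    "compose_zones",
    "zonal_label_mask",
    "mask_to_mesh",
    "segment_volume",
]


@dataclass(frozen=True)
class ReconstructionConfig:
    """Output grid and thresholding for cylindrical reconstruction."""

    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    threshold: float = 0.5
    closing_radius_vox: int = 0  # optional morphological closing, off by default

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")

    @classmethod
    def from_volume(cls, vol: Volume3D | SegmentationMask, **kw) -> "ReconstructionConfig":
        return cls(grid_shape=tuple(vol.shape), spacing=vol.spacing,
                   origin=vol.origin, **kw)


def _plane_probability(pred, channel: str) -> np.ndarray:
    if hasattr(pred, "prostate_prob"):
        return pred.prostate_prob if channel == "prostate" else pred.zone_prob
    return np.asarray(pred, dtype=float)


def reconstruct_probability(
    predictions, geom: RadialGeometry, cfg: ReconstructionConfig,
    channel: str = "prostate",
) -> np.ndarray:
    """Blended probability field on the output grid (before thresholding)."""
    if channel not in ("prostate", "zone"):
        raise ValueError("channel must be 'prostate' or 'zone'")
    n = geom.n_planes
    if len(predictions) != n:
        raise ValueError(f"need {n} plane predictions, got {len(predictions)}")
    planes = [np.asarray(_plane_probability(p, channel), dtype=np.float64)
              for p in predictions]
    n_s, n_z = len(geom.s_coords), len(geom.z_coords)
    for p in planes:
        if p.shape != (n_s, n_z):
            raise ValueError(f"plane shape {p.shape} != geometry grid ({n_s}, {n_z})")

    nx, ny, nz = cfg.grid_shape
    sp = np.asarray(cfg.spacing)
    orig = np.asarray(cfg.origin)
    xs = orig[0] + np.arange(nx) * sp[0]
    ys = orig[1] + np.arange(ny) * sp[1]
    zs = orig[2] + np.arange(nz) * sp[2]

    dx = (xs - geom.axis_point[0])[:, None]
    dy = (ys - geom.axis_point[1])[None, :]
    r = np.sqrt(dx * dx + dy * dy)  # (nx, ny)
    theta = np.mod(np.arctan2(np.broadcast_to(dy, r.shape), np.broadcast_to(dx, r.shape)),
                   2.0 * np.pi)
    # fractional z index into the plane grid (shared by all planes)
    z_idx = np.clip((zs - geom.z_min) / geom.in_plane_spacing, 0, n_z - 1)

    delta = np.deg2rad(geom.angular_interval)
    u = theta / delta  # continuous half-plane slot coordinate in [0, 2n)
    j0 = np.floor(u).astype(int) % (2 * n)
    frac = u - np.floor(u)
    centre_idx = (n_s - 1) / 2.0
    r_idx = r / geom.in_plane_spacing  # offset from the axis column in pixels

    out = np.zeros((nx, ny, nz))
    flat_j0 = j0.ravel()
    flat_frac = frac.ravel()
    flat_ridx = r_idx.ravel()
    vals = np.zeros((r.size, nz))
    for j in range(2 * n):
        k = j % n
        sign = 1.0 if j < n else -1.0
        k_next = (j + 1) % n
        sign_next = 1.0 if (j + 1) % (2 * n) < n else -1.0
        sel = flat_j0 == j
        if not sel.any():
            continue
        s_idx0 = np.clip(centre_idx + sign * flat_ridx[sel], 0, n_s - 1)
        s_idx1 = np.clip(centre_idx + sign_next * flat_ridx[sel], 0, n_s - 1)
        grid0 = np.broadcast_to(s_idx0[:, None], (sel.sum(), nz))
        grid1 = np.broadcast_to(s_idx1[:, None], (sel.sum(), nz))
        zg = np.broadcast_to(z_idx[None, :], (sel.sum(), nz))
        v0 = ndimage.map_coordinates(planes[k], [grid0, zg], order=1, mode="nearest")
        v1 = ndimage.map_coordinates(planes[k_next], [grid1, zg], order=1, mode="nearest")
        w = flat_frac[sel][:, None]
        vals[sel] = (1.0 - w) * v0 + w * v1
    out = vals.reshape(nx, ny, nz)
    out[r > geom.plane_half_width] = 0.0
    return out


def reconstruct_mask(
    predictions, geom: RadialGeometry, cfg: ReconstructionConfig,
    channel: str = "prostate",
) -> SegmentationMask:
    """Cylindrically interpolate per-plane predictions into a binary 3D mask."""
    prob = reconstruct_probability(predictions, geom, cfg, channel)
    mask = prob >= cfg.threshold
    if cfg.closing_radius_vox > 0:
        mask = ndimage.binary_closing(mask, iterations=cfg.closing_radius_vox)
    return SegmentationMask(mask.astype(np.uint8), cfg.spacing, cfg.origin)


def compose_zones(
    prostate: SegmentationMask, tz_raw: SegmentationMask
) -> tuple[SegmentationMask, SegmentationMask]:
    """Restrict the raw TZ channel to the gland and derive the PZ.

    Returns ``(tz, pz)`` with ``tz = tz_raw ∩ prostate`` and
    ``pz = prostate ∖ tz``, so ``pz ∪ tz = prostate`` and ``pz ∩ tz = ∅``
    hold exactly for any inputs.
    """
    if not prostate.same_grid(tz_raw):
        raise ValueError("prostate and TZ masks are on different grids")
    gland = prostate.foreground()
    tz = gland & tz_raw.foreground()
    pz = gland & ~tz
    return (
        SegmentationMask(tz.astype(np.uint8), prostate.spacing, prostate.origin),
        SegmentationMask(pz.astype(np.uint8), prostate.spacing, prostate.origin),
    )


def zonal_label_mask(tz: SegmentationMask, pz: SegmentationMask) -> SegmentationMask:
    """Combine zone masks into one {0: background, 1: TZ, 2: PZ} label volume."""
    if not tz.same_grid(pz):
        raise ValueError("zone masks are on different grids")
    labels = np.zeros(tz.shape, dtype=np.uint8)
    labels[tz.foreground()] = 1
    labels[pz.foreground()] = 2
    return SegmentationMask(labels, tz.spacing, tz.origin,
                            label_set=frozenset({0, 1, 2}))


def mask_to_mesh(mask: SegmentationMask, smooth_sigma_vox: float = 0.6) -> Mesh:
    """Closed triangulated isosurface (0.5 level) of a binary mask, in world
    coordinates (mm).

    The indicator is lightly Gaussian-smoothed before marching cubes so the
    surface does not carry the voxel staircase (which would overestimate
    surface area); the mask is zero-padded by one voxel so surfaces touching
    the volume border are closed."""
    fg = mask.foreground()
    if not fg.any():
        raise ValueError("cannot mesh an empty mask")
    padded = np.pad(fg.astype(np.float32), 2)
    if smooth_sigma_vox > 0:
        padded = ndimage.gaussian_filter(padded, smooth_sigma_vox)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=mask.spacing)
    verts = verts - 2 * np.asarray(mask.spacing) + np.asarray(mask.origin)
    return Mesh(vertices=verts, faces=faces)


def segment_volume(model, vol: Volume3D, geom: RadialGeometry,
                   cfg: ReconstructionConfig | None = None):
    """Full inference pipeline for one volume: radial resampling, per-plane
    network prediction, cylindrical reconstruction, zone composition.

    Returns ``(prostate, tz, pz)`` masks on the configured output grid.
    """
    from .radial_geometry import extract_stack
    from .seg_model import predict_stack

    if cfg is None:
        cfg = ReconstructionConfig.from_volume(vol)
    stack = extract_stack(vol, geom)
    preds = predict_stack(model, stack)
    prostate = reconstruct_mask(preds, geom, cfg, channel="prostate")
    tz_raw = reconstruct_mask(preds, geom, cfg, channel="zone")
    tz, pz = compose_zones(prostate, tz_raw)
    return prostate, tz, pz
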