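"""Radial plane resampling around the probe axis.

A transrectal 3D sweep covers a roughly cylindrical field of view whose axis
is the probe's z axis.  Instead of segmenting axial slices, the pipeline
resamples the volume into *radial* planes: 2D planes that each contain the
cylinder axis, at fixed angular steps.  With the default 10° step, 18 planes
cover the whole cylinder (each plane covers its angle with positive in-plane
radius ``s`` and the opposite angle, 180° away, with negative ``s``).

Each radial plane is accompanied by two parallel *context* planes offset by
``context_offset`` mm along the plane normal; the segmentation network sees
all three as channels, which stabilises predictions between adjacent planes.

Coordinate convention: a plane-grid point ``(s, z)`` of plane ``k`` (angle
``theta_k = k * angular_interval``) maps to world

    (axis_x + s*cos(theta_k), axis_y + s*sin(theta_k), z)

so the ``s = 0`` column is the cylinder axis for every plane.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .volume_io import SegmentationMask, Volume3D

__all__ = [
    "RadialGeometry",
    "PlaneImage",
    "RadialPlaneStack",
    "plane_count",
    "extract_plane",
    "extract_context",
    "extract_stack",
    "plane_point_to_world",
    "slice_mask",
]


def plane_count(angular_interval: float) -> int:
    """Number of radial planes covering the full cylinder at the given
    angular step in degrees (e.g. 10° -> 18 planes)."""
    if not (0 < angular_interval <= 180):
        raise ValueError(f"angular_interval must be in (0, 180], got {angular_interval}")
    n = 180.0 / angular_interval
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"angular_interval must divide 180 exactly, got {angular_interval}")
    return int(round(n))


@dataclass(frozen=True)
class RadialGeometry:
    """Sampling geometry of the radial plane fan.

    Attributes
    ----------
    axis_point:
        World (x, y) position in mm the cylinder axis passes through; the
        axis direction is the volume's z axis.
    angular_interval:
        Degrees between consecutive planes; must divide 180.
    plane_half_width:
        Maximum |s| sampled, mm.
    z_min, z_max:
        Axial sampling range, mm (world coordinates).
    in_plane_spacing:
        Pixel step of the plane grid in both s and z, mm.
    context_offset:
        Distance of each parallel context plane from the central plane, mm.
    """

    axis_point: tuple[float, float]
    angular_interval: float = 10.0
    plane_half_width: float = 30.0
    z_min: float = 0.0
    z_max: float = 60.0
    in_plane_spacing: float = 0.5
    context_offset: float = 4.0

    def __post_init__(self) -> None:
        plane_count(self.angular_interval)  # validates divisibility
        if self.in_plane_spacing <= 0:
            raise ValueError("in_plane_spacing must be > 0")
        if self.context_offset < 0:
            raise ValueError("context_offset must be >= 0")
        if self.plane_half_width <= 0:
            raise ValueError("plane_half_width must be > 0")
        if self.z_max <= self.z_min:
            raise ValueError("z_max must exceed z_min")

    @property
    def n_planes(self) -> int:
        return plane_count(self.angular_interval)

    def angle_rad(self, k: int) -> float:
        return np.deg2rad(k * self.angular_interval)

    @property
    def s_coords(self) -> np.ndarray:
        """Signed in-plane radii, symmetric about s = 0 (axis column)."""
        n = int(np.floor(self.plane_half_width / self.in_plane_spacing + 1e-9))
        return np.arange(-n, n + 1) * self.in_plane_spacing

    @property
    def z_coords(self) -> np.ndarray:
        n = int(np.floor((self.z_max - self.z_min) / self.in_plane_spacing + 1e-9))
        return self.z_min + np.arange(n + 1) * self.in_plane_spacing

    def with_interval(self, angular_interval: float) -> "RadialGeometry":
        return replace(self, angular_interval=angular_interval)

    @classmethod
    def from_volume(
        cls,
        vol: Volume3D | SegmentationMask,
        angular_interval: float = 10.0,
        in_plane_spacing: float = 0.5,
        context_offset: float = 4.0,
    ) -> "RadialGeometry":
        """Default geometry: axis through the xy-centre, full z extent,
        half-width reaching the nearest lateral face."""
        lower = np.asarray(vol.origin, dtype=float)
        upper = lower + (np.array(vol.shape) - 1) * np.asarray(vol.spacing)
        centre = (lower + upper) / 2.0
        half_width = float(min(upper[0] - centre[0], upper[1] - centre[1]))
        return cls(
            axis_point=(float(centre[0]), float(centre[1])),
            angular_interval=angular_interval,
            plane_half_width=half_width,
            z_min=float(lower[2]),
            z_max=float(upper[2]),
            in_plane_spacing=in_plane_spacing,
            context_offset=context_offset,
        )


@dataclass
class PlaneImage:
    """A resampled 2D radial plane, indexed ``pixels[s_index, z_index]``."""

    pixels: np.ndarray
    s: np.ndarray  # signed in-plane radii, mm
    z: np.ndarray  # axial positions, mm
    plane_index: int
    angle_deg: float


@dataclass
class RadialPlaneStack:
    """The full fan: one (center, context-, context+) triple per angle."""

    planes: list[tuple[PlaneImage, PlaneImage, PlaneImage]]
    geometry: RadialGeometry
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.planes) != self.geometry.n_planes:
            raise ValueError(
                f"expected {self.geometry.n_planes} plane triples, got {len(self.planes)}"
            )

    def __len__(self) -> int:
        return len(self.planes)


def plane_point_to_world(
    geom: RadialGeometry, k: int, s: float | np.ndarray, z: float | np.ndarray
) -> np.ndarray:
    """Inverse map: plane-grid point ``(s, z)`` of plane ``k`` -> world (mm)."""
    _check_plane_index(geom, k)
    theta = geom.angle_rad(k)
    s = np.asarray(s, dtype=float)
    z = np.asarray(z, dtype=float)
    x = geom.axis_point[0] + s * np.cos(theta)
    y = geom.axis_point[1] + s * np.sin(theta)
    return np.stack(np.broadcast_arrays(x, y, z), axis=-1)


def _check_plane_index(geom: RadialGeometry, k: int) -> None:
    if not (0 <= k < geom.n_planes):
        raise ValueError(f"plane index {k} outside [0, {geom.n_planes})")


def _sample_world(vol: Volume3D, points: np.ndarray) -> np.ndarray:
    """Trilinear sampling at world points (..., 3); out-of-volume samples are
    edge-replicated."""
    idx = vol.world_to_index(points)
    coords = [idx[..., a].ravel() for a in range(3)]
    values = map_coordinates(
        vol.voxels.astype(np.float64, copy=False), coords, order=1, mode="nearest"
    )
    return values.reshape(points.shape[:-1])


def _plane_world_grid(geom: RadialGeometry, k: int, normal_offset: float = 0.0) -> np.ndarray:
    theta = geom.angle_rad(k)
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    normal = np.array([-np.sin(theta), np.cos(theta), 0.0])
    s = geom.s_coords
    z = geom.z_coords
    S, Z = np.meshgrid(s, z, indexing="ij")
    pts = (
        np.array([geom.axis_point[0], geom.axis_point[1], 0.0])
        + S[..., None] * direction
        + normal_offset * normal
    )
    pts = pts.copy()
    pts[..., 2] = Z
    return pts


def extract_plane(vol: Volume3D, geom: RadialGeometry, k: int) -> PlaneImage:
    """Resample the radial plane at angle ``k * angular_interval`` by
    trilinear interpolation."""
    _check_plane_index(geom, k)
    pts = _plane_world_grid(geom, k)
    pixels = _sample_world(vol, pts)
    return PlaneImage(pixels=pixels, s=geom.s_coords, z=geom.z_coords,
                      plane_index=k, angle_deg=k * geom.angular_interval)


def extract_context(
    vol: Volume3D, geom: RadialGeometry, k: int
) -> tuple[PlaneImage, PlaneImage]:
    """The two planes parallel to plane ``k`` at ∓/± ``context_offset`` mm
    along the plane normal, on the same (s, z) grid."""
    _check_plane_index(geom, k)
    out = []
    for sign in (-1.0, +1.0):
        pts = _plane_world_grid(geom, k, normal_offset=sign * geom.context_offset)
        pixels = _sample_world(vol, pts)
        out.append(PlaneImage(pixels=pixels, s=geom.s_coords, z=geom.z_coords,
                              plane_index=k, angle_deg=k * geom.angular_interval))
    return out[0], out[1]


def extract_stack(vol: Volume3D, geom: RadialGeometry, source_id: str = "") -> RadialPlaneStack:
    """Extract all ``n_planes`` (center, context-, context+) triples."""
    planes = []
    for k in range(geom.n_planes):
        centre = extract_plane(vol, geom, k)
        ctx_minus, ctx_plus = extract_context(vol, geom, k)
        planes.append((centre, ctx_minus, ctx_plus))
    return RadialPlaneStack(planes=planes, geometry=geom, source_id=source_id)


def slice_mask(mask: SegmentationMask, geom: RadialGeometry, k: int,
               label: int | None = None) -> np.ndarray:
    """Binary plane mask: trilinear sampling of the indicator followed by a
    0.5 threshold (deterministic, smooth boundary handling)."""
    indicator = mask.foreground(label).astype(np.float64)
    vol = Volume3D(indicator, mask.spacing, mask.origin)
    plane = extract_plane(vol, geom, k)
    return plane.pixels > 0.5
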