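"""Volumetric image I/O and basic containers.

Volumes are held as axis-aligned voxel grids in ``(x, y, z)`` index order with
physical spacing and origin in millimetres.  The world position of voxel
``(i, j, k)`` is ``origin + (i, j, k) * spacing`` (node-centred, 0-based).
Supported on-disk formats are NIfTI (``.nii``/``.nii.gz``) and MetaImage
(``.mha``/``.mhd``); surface meshes export to STL or PLY.

4D contrast-enhanced ultrasound (CEUS) acquisitions are collapsed to a single
3D volume by per-voxel temporal averaging of the frame intensities
(:func:`temporal_mean`), which is the representation the segmentation pipeline
consumes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import SimpleITK as sitk
import trimesh

__all__ = [
    "Volume3D",
    "Volume4D",
    "SegmentationMask",
    "Mesh",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "temporal_mean",
    "export_mesh",
]

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise ValueError(
            f"unsupported volume format {path.suffix!r}; "
            f"expected one of {_VOLUME_SUFFIXES}"
        )


@dataclass
class Volume3D:
    """A 3D scalar image on an axis-aligned grid.

    Parameters
    ----------
    voxels:
        Array of shape ``(nx, ny, nz)``; arbitrary intensity units.
    spacing:
        Per-axis voxel size in mm, all components positive.
    origin:
        World position (mm) of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 2:
            raise ValueError(f"grid dimensions must be >= 2 per axis, got {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def world_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (lower, upper) world coordinates of the grid nodes, mm."""
        lower = np.asarray(self.origin, dtype=float)
        upper = lower + (np.array(self.shape) - 1) * np.asarray(self.spacing)
        return lower, upper

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates (..., 3) in mm to fractional voxel indices."""
        points = np.asarray(points, dtype=float)
        return (points - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_grid(self, other: "Volume3D | SegmentationMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class Volume4D:
    """An ordered sequence of co-registered :class:`Volume3D` frames."""

    frames: Sequence[Volume3D]
    frame_times: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("a 4D sequence needs at least one frame")
        first = self.frames[0]
        for f in self.frames[1:]:
            if not first.same_grid(f):
                raise ValueError("all frames must share dimensions, spacing and origin")
        if self.frame_times is not None and len(self.frame_times) != len(self.frames):
            raise ValueError("frame_times length must match number of frames")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class SegmentationMask:
    """An integer label grid aligned to a :class:`Volume3D`.

    Binary masks use labels {0, 1} (background / foreground); zonal masks use
    {0, 1, 2} for background / transition zone (TZ) / peripheral zone (PZ).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_set: frozenset[int] = field(default_factory=lambda: frozenset({0, 1}))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D label array, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.issubdtype(self.labels.dtype, np.bool_):
                self.labels = self.labels.astype(np.uint8)
            else:
                raise ValueError("mask labels must be integers")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")
        self.label_set = frozenset(int(v) for v in self.label_set)
        present = set(np.unique(self.labels).tolist())
        if not present <= self.label_set:
            raise ValueError(
                f"labels {sorted(present - self.label_set)} outside declared set "
                f"{sorted(self.label_set)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def foreground(self, label: int | None = None) -> np.ndarray:
        """Boolean array of the given label (default: anything non-zero)."""
        if label is None:
            return self.labels > 0
        return self.labels == label

    def same_grid(self, other: "SegmentationMask | Volume3D") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class Mesh:
    """Triangle surface mesh in world coordinates (mm)."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face indices out of vertex range")
            a, b, c = self.faces.T
            if np.any((a == b) | (b == c) | (a == c)):
                raise ValueError("degenerate face with repeated vertex")


def _to_sitk(voxels: np.ndarray, spacing, origin) -> sitk.Image:
    # SimpleITK arrays are (z, y, x); ours are (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _resample_to_identity(img: sitk.Image) -> sitk.Image:
    """Resample an image with non-identity direction cosines onto an
    axis-aligned grid (trilinear interpolation)."""
    out = sitk.Image(img.GetSize(), img.GetPixelID())
    out.SetSpacing(img.GetSpacing())
    out.SetOrigin(img.GetOrigin())
    return sitk.Resample(img, out, sitk.Transform(), sitk.sitkLinear, 0.0)


def read_volume(path: str | os.PathLike) -> Volume3D:
    """Read a NIfTI or MetaImage volume.

    Orientation beyond origin/spacing is normalised: images carrying
    non-identity direction cosines are resampled onto an axis-aligned grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    _check_suffix(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"expected a 3D image, got {img.GetDimension()}D")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        img = _resample_to_identity(img)
    voxels = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return Volume3D(voxels=voxels, spacing=img.GetSpacing(), origin=img.GetOrigin())


def write_volume(vol: Volume3D, path: str | os.PathLike) -> None:
    """Write a volume to NIfTI or MetaImage; round-trips losslessly for the
    supported scalar types."""
    path = Path(path)
    _check_suffix(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    try:
        sitk.WriteImage(_to_sitk(vol.voxels, vol.spacing, vol.origin), str(path))
    except RuntimeError as exc:  # unwritable location etc.
        raise OSError(f"could not write {path}: {exc}") from exc


def read_mask(path: str | os.PathLike, label_set=frozenset({0, 1})) -> SegmentationMask:
    """Read an integer label volume."""
    vol = read_volume(path)
    labels = vol.voxels
    if not np.issubdtype(labels.dtype, np.integer):
        labels = np.rint(labels).astype(np.int16)
    return SegmentationMask(labels=labels, spacing=vol.spacing, origin=vol.origin,
                            label_set=label_set)


def write_mask(mask: SegmentationMask, path: str | os.PathLike) -> None:
    vol = Volume3D(mask.labels.astype(np.uint8), mask.spacing, mask.origin)
    write_volume(vol, path)


def temporal_mean(seq: Volume4D) -> Volume3D:
    """Collapse a 4D CEUS acquisition to a 3D mean-intensity volume.

    Each output voxel is the arithmetic mean of that voxel's intensity over
    all frames; the grid geometry is inherited from the frames.
    """
    stack = np.stack([f.voxels for f in seq.frames], axis=0)
    mean = stack.mean(axis=0, dtype=np.float64)
    first = seq.frames[0]
    return Volume3D(voxels=mean, spacing=first.spacing, origin=first.origin)


def export_mesh(mesh: Mesh, path: str | os.PathLike) -> None:
    """Export a triangle mesh to STL or PLY."""
    if len(mesh.faces) == 0 or len(mesh.vertices) == 0:
        raise ValueError("cannot export an empty mesh")
    path = Path(path)
    if path.suffix.lower() not in (".stl", ".ply"):
        raise ValueError(f"unsupported mesh format {path.suffix!r}; use .stl or .ply")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))


def load_mesh(path: str | os.PathLike) -> Mesh:
    """Read back an STL/PLY mesh (mainly for round-trip checks)."""
    tm = trimesh.load_mesh(str(path), process=False)
    return Mesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))
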