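"""Overlap and surface agreement metrics for segmentation evaluation.

Implements the metric family used to compare automated and manual prostate
segmentations: Dice similarity coefficient (DSC), intersection over union
(IoU), relative volume difference (RVD, %), mean surface distance (MSD, mm)
and Hausdorff distance (HD, mm), in both 3D (volume masks) and 2D (per radial
plane, averaged over the fan), with per-case aggregation as mean and 95%
Student-t confidence intervals.

Conventions fixed here so results are oracle-checkable:

* surfaces are the centres of foreground voxels with at least one
  six-connected background neighbour (volume border counts as background);
* MSD is the symmetric average of the two directed mean nearest-neighbour
  distances; HD is the exact symmetric maximum (worst-case agreement, not a
  percentile);
* a pair of *both-empty* masks scores DSC = IoU = 1 (trivial perfect
  agreement); a one-empty pair scores 0 and has undefined surface distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .volume_io import SegmentationMask

__all__ = [
    "dice",
    "iou",
    "rvd",
    "surface_distances",
    "per_plane_metrics",
    "aggregate",
    "CaseMetrics",
]


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, SegmentationMask):
        return mask.foreground()
    return np.asarray(mask).astype(bool)


def _check_same_grid(a, b) -> None:
    if isinstance(a, SegmentationMask) and isinstance(b, SegmentationMask):
        if not a.same_grid(b):
            raise ValueError("masks are on different grids")
    else:
        if _as_bool(a).shape != _as_bool(b).shape:
            raise ValueError("masks have different shapes")


def dice(a, b) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); 1 if both empty."""
    _check_same_grid(a, b)
    A, B = _as_bool(a), _as_bool(b)
    na, nb = int(A.sum()), int(B.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((A & B).sum()) / (na + nb)


def iou(a, b) -> float:
    """Intersection over union |A∩B| / |A∪B|; 1 if both empty."""
    _check_same_grid(a, b)
    A, B = _as_bool(a), _as_bool(b)
    union = int((A | B).sum())
    if union == 0:
        return 1.0
    return int((A & B).sum()) / union


def rvd(auto, manual) -> float:
    """Relative volume difference (V_auto − V_manual) / V_manual × 100.

    Positive when the automated mask over-segments the reference.
    """
    _check_same_grid(auto, manual)
    va = int(_as_bool(auto).sum())
    vm = int(_as_bool(manual).sum())
    if vm == 0:
        raise ValueError("reference (manual) mask is empty; RVD undefined")
    return (va - vm) / vm * 100.0


def _surface_points(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """World coordinates (mm) of boundary voxel centres.

    Boundary = foreground voxels with >=1 face-connected background
    neighbour; voxels on the array border are boundary.
    """
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    surf = mask & ~eroded
    idx = np.argwhere(surf)
    return idx * spacing


def surface_distances(a, b, spacing=None) -> tuple[float, float]:
    """Return ``(msd, hd)`` in mm between the surfaces of two masks.

    MSD: symmetric average of the two directed mean nearest-neighbour
    distances.  HD: maximum over both directed Hausdorff distances.
    """
    _check_same_grid(a, b)
    if spacing is None:
        if isinstance(a, SegmentationMask):
            spacing = a.spacing
        else:
            spacing = (1.0,) * _as_bool(a).ndim
    A, B = _as_bool(a), _as_bool(b)
    if not A.any() or not B.any():
        raise ValueError("surface distances undefined for an empty mask")
    sp = np.asarray(spacing, dtype=float)
    pa = _surface_points(A, sp)
    pb = _surface_points(B, sp)
    d_ab, _ = cKDTree(pb).query(pa)
    d_ba, _ = cKDTree(pa).query(pb)
    msd = 0.5 * (d_ab.mean() + d_ba.mean())
    hd = max(d_ab.max(), d_ba.max())
    return float(msd), float(hd)


@dataclass
class CaseMetrics:
    """One case's metric set for one structure at one dimensionality."""

    dsc: float
    iou: float
    rvd: float | None
    msd: float | None
    hd: float | None


def case_metrics(pred, truth, spacing=None) -> CaseMetrics:
    """All five metrics for one mask pair (surface/RVD values are ``None``
    where undefined, i.e. an empty mask is involved)."""
    d = dice(pred, truth)
    j = iou(pred, truth)
    P, T = _as_bool(pred), _as_bool(truth)
    r = rvd(pred, truth) if T.any() else None
    if P.any() and T.any():
        msd, hd = surface_distances(pred, truth, spacing)
    else:
        msd = hd = None
    return CaseMetrics(dsc=d, iou=j, rvd=r, msd=msd, hd=hd)


def per_plane_metrics(pred_planes, truth_planes, pixel_spacing: float = 1.0) -> CaseMetrics:
    """2D metrics per radial plane, averaged over the fan of one case.

    Each plane pair contributes pixel-set overlap metrics and boundary-curve
    surface distances (2D analogues of the 3D definitions); the case value is
    the arithmetic mean over planes.  Planes where a metric is undefined
    (either mask empty for surface distances / empty reference for RVD) are
    excluded from that metric's mean.
    """
    if len(pred_planes) != len(truth_planes):
        raise ValueError(
            f"plane count mismatch: {len(pred_planes)} vs {len(truth_planes)}"
        )
    if len(pred_planes) == 0:
        raise ValueError("no planes given")
    dscs, ious, rvds, msds, hds = [], [], [], [], []
    sp = (pixel_spacing, pixel_spacing)
    for p, t in zip(pred_planes, truth_planes):
        P, T = _as_bool(p), _as_bool(t)
        dscs.append(dice(P, T))
        ious.append(iou(P, T))
        if T.any():
            rvds.append(rvd(P, T))
        if P.any() and T.any():
            msd, hd = surface_distances(P, T, sp)
            msds.append(msd)
            hds.append(hd)
    return CaseMetrics(
        dsc=float(np.mean(dscs)),
        iou=float(np.mean(ious)),
        rvd=float(np.mean(rvds)) if rvds else None,
        msd=float(np.mean(msds)) if msds else None,
        hd=float(np.mean(hds)) if hds else None,
    )


def aggregate(values) -> tuple[float, float, float]:
    """Mean and 95% Student-t confidence interval over per-case values.

    With fewer than two cases the mean is still returned but the CI is
    undefined and reported as NaN.
    """
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    if vals.size == 0:
        raise ValueError("no values to aggregate")
    mean = float(vals.mean())
    if vals.size < 2:
        return mean, float("nan"), float("nan")
    sem = vals.std(ddof=1) / np.sqrt(vals.size)
    tcrit = stats.t.ppf(0.975, vals.size - 1)
    return mean, float(mean - tcrit * sem), float(mean + tcrit * sem)
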