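"""Prostate volume estimates and paired agreement statistics.

Gland volume is clinically central (PSA density = serum PSA / prostate
volume).  This module computes volumes from segmentation masks (voxel
counting) and from the triaxial ellipsoid formula used with MRI diameters,

    V = (pi / 6) * length * width * height  [cm^3],

and compares two paired volume series with Bland-Altman bias / limits of
agreement and the squared Pearson correlation R^2.

Sign convention: differences are ``volume_b - volume_a`` with series *b* the
reference-style estimate (e.g. MRI ellipsoid) and series *a* the automated
one, so a larger reference volume yields a positive bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .volume_io import SegmentationMask

__all__ = [
    "VolumePair",
    "AgreementReport",
    "mask_volume",
    "ellipsoid_volume",
    "psa_density",
    "bland_altman",
    "r_squared",
    "stratify_by_volume",
    "STRATUM_SMALL_MAX",
    "STRATUM_LARGE_MIN",
]

# Volume strata cut-offs in cm^3: small < 40, medium 40-70 (inclusive), large > 70
STRATUM_SMALL_MAX = 40.0
STRATUM_LARGE_MIN = 70.0


@dataclass
class VolumePair:
    case_id: str
    volume_a: float  # cm^3, e.g. mask-derived (automated)
    volume_b: float  # cm^3, e.g. ellipsoid-formula (MRI-style)
    psa: float | None = None  # ng/ml

    def __post_init__(self) -> None:
        if self.volume_a <= 0 or self.volume_b <= 0:
            raise ValueError("volumes must be positive")


@dataclass
class AgreementReport:
    bias: float  # mean(b - a), cm^3
    loa_low: float  # bias - 1.96 * SD of differences
    loa_high: float  # bias + 1.96 * SD of differences
    differences: np.ndarray = field(repr=False)
    averages: np.ndarray = field(repr=False)  # (a + b) / 2, plot abscissa


def mask_volume(mask: SegmentationMask) -> float:
    """Foreground volume in cm^3 (voxel count x voxel volume)."""
    n = int(mask.foreground().sum())
    return n * mask.voxel_volume_mm3 / 1000.0


def ellipsoid_volume(length: float, width: float, height: float) -> float:
    """Ellipsoid-formula volume (pi/6 * L * W * H) from three orthogonal
    diameters in cm; returns cm^3."""
    if length < 0 or width < 0 or height < 0:
        raise ValueError("dimensions must be non-negative")
    return np.pi / 6.0 * length * width * height


def psa_density(psa: float, volume: float) -> float:
    """PSA density in ng/ml/cm^3."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return psa / volume


def bland_altman(pairs: list[VolumePair]) -> AgreementReport:
    """Bland-Altman agreement: bias = mean(b - a); limits of agreement =
    bias ± 1.96 x sample SD of the differences."""
    if len(pairs) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    a = np.array([p.volume_a for p in pairs], dtype=float)
    b = np.array([p.volume_b for p in pairs], dtype=float)
    d = b - a
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementReport(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        differences=d,
        averages=(a + b) / 2.0,
    )


def r_squared(pairs: list[VolumePair]) -> float:
    """Squared Pearson correlation of the two volume series."""
    if len(pairs) < 3:
        raise ValueError("R^2 needs at least 3 pairs")
    a = np.array([p.volume_a for p in pairs], dtype=float)
    b = np.array([p.volume_b for p in pairs], dtype=float)
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValueError("R^2 undefined for a zero-variance series")
    r, _ = stats.pearsonr(a, b)
    return float(r * r)


def stratify_by_volume(volumes) -> list[str]:
    """Assign each volume (cm^3) to 'small' (<40), 'medium' (40-70,
    boundaries inclusive) or 'large' (>70)."""
    out = []
    for v in volumes:
        if v < 0:
            raise ValueError("volumes must be non-negative")
        if v < STRATUM_SMALL_MAX:
            out.append("small")
        elif v <= STRATUM_LARGE_MIN:
            out.append("medium")
        else:
            out.append("large")
    return out
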