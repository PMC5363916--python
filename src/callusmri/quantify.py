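"""Callus measurements: 3D bone volume, 2D histomorphometric fractions,
μCT bone volume with density calibration, and resolution ratios.

Units follow the reporting convention of murine fracture-healing studies:
volumes in mm³, areas in mm², tissue fractions in percent of total callus
area (TA).  Internally all grids are in μm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import CallusVOI
from .volume import (
    ImageVolume,
    LabelVolume,
    SegClass,
    ValidationError,
    GridMismatchError,
)

__all__ = [
    "QuantReport",
    "DensityCalibration",
    "UCT_BONE_THRESHOLD_MG_HA_CM3",
    "bone_volume_3d",
    "callus_area_2d",
    "tissue_fractions_2d",
    "quantify_slices",
    "calibrate_density",
    "uct_bone_volume",
    "resolution_ratio",
    "reports_to_frame",
]

#: Global mineralization threshold separating mineralized from
#: non-mineralized tissue in calibrated μCT volumes.
UCT_BONE_THRESHOLD_MG_HA_CM3: float = 642.0

_UM3_PER_MM3 = 1e9
_UM2_PER_MM2 = 1e6


@dataclass
class QuantReport:
    """Per-specimen measurement row (one method, one healing day)."""

    specimen_id: str
    healing_day: int
    method: str  # "MRI" | "uCT" | "histology"
    BV_mm3: float | None = None
    TA_mm2: float | None = None
    BA_TA_pct: float | None = None
    CA_TA_pct: float | None = None
    FA_TA_pct: float | None = None
    unclassified_TA_pct: float | None = None

    def __post_init__(self) -> None:
        if self.BV_mm3 is not None and self.BV_mm3 < 0:
            raise ValidationError("BV must be >= 0")
        if self.TA_mm2 is not None and self.TA_mm2 < 0:
            raise ValidationError("TA must be >= 0")
        fracs = [self.BA_TA_pct, self.CA_TA_pct, self.FA_TA_pct, self.unclassified_TA_pct]
        if all(f is not None for f in fracs):
            for f in fracs:
                if not 0.0 <= f <= 100.0 + 1e-9:
                    raise ValidationError("tissue fractions must be in [0, 100] percent")
            if self.TA_mm2 and abs(sum(fracs) - 100.0) > 1e-6:
                raise ValidationError("tissue fractions must sum to 100% of TA")

    def to_row(self) -> dict:
        return {
            "specimen_id": self.specimen_id,
            "healing_day": self.healing_day,
            "method": self.method,
            "BV_mm3": self.BV_mm3,
            "TA_mm2": self.TA_mm2,
            "BA_TA_pct": self.BA_TA_pct,
            "CA_TA_pct": self.CA_TA_pct,
            "FA_TA_pct": self.FA_TA_pct,
            "unclassified_TA_pct": self.unclassified_TA_pct,
        }


def reports_to_frame(reports) -> pd.DataFrame:
    """Stack :class:`QuantReport` rows into a tidy DataFrame."""
    return pd.DataFrame([r.to_row() for r in reports])


def bone_volume_3d(labels: LabelVolume, voi: CallusVOI) -> float:
    """Bone volume (mm³): bone-classified voxels inside the VOI × voxel volume."""
    if not voi.same_grid(labels):
        raise GridMismatchError("VOI and label volume must share one grid")
    n = int(np.count_nonzero((labels.labels == int(SegClass.BONE)) & voi.mask))
    return n * labels.voxel_volume_um3 / _UM3_PER_MM3


def callus_area_2d(slice_labels: np.ndarray, spacing: tuple[float, float]) -> float:
    """Total callus area TA (mm²) of one section: non-background pixels × pixel area."""
    slice_labels = np.asarray(slice_labels)
    if slice_labels.ndim != 2:
        raise ValidationError("slice_labels must be 2D")
    if any(s <= 0 for s in spacing):
        raise ValidationError("pixel spacing must be strictly positive")
    n = int(np.count_nonzero(slice_labels != int(SegClass.BACKGROUND)))
    if n == 0:
        warnings.warn("empty callus slice: TA = 0")
    return n * float(spacing[0]) * float(spacing[1]) / _UM2_PER_MM2


def tissue_fractions_2d(
    slice_labels: np.ndarray, spacing: tuple[float, float] | None = None
) -> dict[str, float]:
    """Per-class area fractions (percent of TA) of one section.

    Returns BA/TA (bone), CA/TA (cartilage), FA/TA (fibrous/marrow) and the
    unclassified remainder; the four always sum to 100.
    """
    slice_labels = np.asarray(slice_labels)
    if slice_labels.ndim != 2:
        raise ValidationError("slice_labels must be 2D")
    total = int(np.count_nonzero(slice_labels != int(SegClass.BACKGROUND)))
    if total == 0:
        raise ValidationError("TA is zero: tissue fractions are undefined")
    counts = {
        "BA_TA_pct": int(np.count_nonzero(slice_labels == int(SegClass.BONE))),
        "CA_TA_pct": int(np.count_nonzero(slice_labels == int(SegClass.CARTILAGE))),
        "FA_TA_pct": int(np.count_nonzero(slice_labels == int(SegClass.FIBROUS_OR_MARROW))),
        "unclassified_TA_pct": int(np.count_nonzero(slice_labels == int(SegClass.UNCLASSIFIED))),
    }
    return {k: 100.0 * v / total for k, v in counts.items()}


def quantify_slices(slices, spacing: tuple[float, float]) -> dict[str, float]:
    """Mean TA and tissue fractions over the (two) central slices."""
    tas = [callus_area_2d(s, spacing) for s in slices]
    fracs = [tissue_fractions_2d(s) for s in slices]
    out = {"TA_mm2": float(np.mean(tas))}
    for key in ("BA_TA_pct", "CA_TA_pct", "FA_TA_pct", "unclassified_TA_pct"):
        out[key] = float(np.mean([f[key] for f in fracs]))
    return out


@dataclass(frozen=True)
class DensityCalibration:
    """Linear raw-value → mineral-density map from two hydroxyapatite phantoms.

    The two calibration phantoms have known densities (250 and 750
    mg HA/cm³ by convention); their measured raw values fix an affine map
    applied voxelwise.
    """

    raw_low: float
    raw_high: float
    density_low: float = 250.0
    density_high: float = 750.0

    def validate(self) -> None:
        if self.raw_low == self.raw_high:
            raise ValidationError("calibration phantom raw values must be distinct")
        if self.density_low >= self.density_high:
            raise ValidationError("calibration densities must be increasing")
        if self.raw_low > self.raw_high:
            raise ValidationError("raw→density map must be strictly monotone increasing")

    @property
    def slope(self) -> float:
        return (self.density_high - self.density_low) / (self.raw_high - self.raw_low)

    def __call__(self, raw):
        self.validate()
        return self.density_low + (np.asarray(raw, dtype=np.float64) - self.raw_low) * self.slope


def calibrate_density(raw_volume: ImageVolume, calib: DensityCalibration) -> ImageVolume:
    """Apply the two-point hydroxyapatite calibration voxelwise (→ mg HA/cm³)."""
    calib.validate()
    return raw_volume.with_values(calib(raw_volume.values))


def uct_bone_volume(
    density_volume: ImageVolume,
    voi: CallusVOI,
    threshold: float = UCT_BONE_THRESHOLD_MG_HA_CM3,
) -> float:
    """Mineralized-tissue volume (mm³): VOI voxels with density ≥ threshold.

    The threshold is inclusive; the result is monotone non-increasing in
    the threshold.
    """
    if not voi.same_grid(density_volume):
        raise GridMismatchError("VOI and density volume must share one grid")
    n = int(np.count_nonzero((density_volume.values >= threshold) & voi.mask))
    return n * density_volume.voxel_volume_um3 / _UM3_PER_MM3


def resolution_ratio(spacing_a, spacing_b) -> tuple[float, ...]:
    """Elementwise voxel-dimension fold ratios spacing_a / spacing_b.

    For the default grids, 52×52×350 μm MRI against 8 μm isotropic μCT,
    this yields (6.5, 6.5, 43.75): the MRI grid is 6.5× coarser in-plane
    and 43.75× coarser in the slice direction.
    """
    a = np.asarray(spacing_a, dtype=np.float64)
    b = np.asarray(spacing_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValidationError("spacing tuples must have equal length")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValidationError("spacings must be strictly positive")
    return tuple(float(r) for r in a / b)
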