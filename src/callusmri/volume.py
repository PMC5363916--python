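"""In-memory containers for scalar image volumes and label maps.

All volumes live on regular, axis-aligned grids with per-axis physical
spacing in micrometres.  Axis order is fixed as (x, y, z) where x is the
femur (bore) axis, y/z are transverse; the MRI slice-normal is z.  World
coordinates of voxel centres are ``origin + index * spacing``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "ValidationError",
    "GridMismatchError",
    "DegenerateDataError",
    "Tissue",
    "SegClass",
    "TISSUE_CODE_TABLE",
    "SEG_CODE_TABLE",
    "TRUTH_TO_SEG",
    "ImageVolume",
    "LabelVolume",
    "require_same_grid",
    "truth_to_seg",
]


class ValidationError(ValueError):
    """An input violates a documented invariant."""


class GridMismatchError(ValueError):
    """Two volumes expected on a shared grid disagree in shape/spacing/origin."""


class DegenerateDataError(ValueError):
    """A statistic is undefined on the given data (e.g. zero variance)."""


class Tissue(IntEnum):
    """Ground-truth tissue codes used by phantoms and label files."""

    BACKGROUND = 0
    CORTEX = 1
    MARROW = 2
    BONE_CALLUS = 3
    CARTILAGE = 4
    FIBROUS = 5
    ARTIFACT = 6
    PIN = 7


class SegClass(IntEnum):
    """Classifier output codes (normalized-intensity bins)."""

    BACKGROUND = 0
    BONE = 1
    FIBROUS_OR_MARROW = 2
    CARTILAGE = 3
    UNCLASSIFIED = 4


TISSUE_CODE_TABLE: dict[int, str] = {int(t): t.name.lower() for t in Tissue}
SEG_CODE_TABLE: dict[int, str] = {int(c): c.name.lower() for c in SegClass}

# Mineralized truth classes (cortex + bony callus) fall in the bone bin; marrow
# and fibrous tissue are iso-intense; artifacts are brighter than every tissue
# bin.  Pins carry no tissue signal and are excluded from any VOI.
TRUTH_TO_SEG: dict[int, int] = {
    int(Tissue.BACKGROUND): int(SegClass.BACKGROUND),
    int(Tissue.CORTEX): int(SegClass.BONE),
    int(Tissue.MARROW): int(SegClass.FIBROUS_OR_MARROW),
    int(Tissue.BONE_CALLUS): int(SegClass.BONE),
    int(Tissue.CARTILAGE): int(SegClass.CARTILAGE),
    int(Tissue.FIBROUS): int(SegClass.FIBROUS_OR_MARROW),
    int(Tissue.ARTIFACT): int(SegClass.UNCLASSIFIED),
    int(Tissue.PIN): int(SegClass.BACKGROUND),
}


def _check_grid(spacing, origin) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    if len(spacing) != 3 or len(origin) != 3:
        raise ValidationError("spacing and origin must be 3-tuples (x, y, z)")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be strictly positive, got {spacing}")
    if any(not np.isfinite(o) for o in origin):
        raise ValidationError(f"origin must be finite, got {origin}")
    return spacing, origin


@dataclass
class ImageVolume:
    """A 3D scalar field (MRI signal intensity or μCT mineral density).

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values.  MRI intensities are arbitrary units; μCT volumes are
        mg HA/cm³ after calibration.
    spacing : 3-tuple of float
        Physical voxel pitch per axis, μm.
    origin : 3-tuple of float
        World coordinate of voxel (0, 0, 0), μm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError(f"values must be 3D, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values must be finite")
        self.spacing, self.origin = _check_grid(self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (μm) of voxel centres along ``axis``."""
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        """A new volume on the same grid with different voxel values."""
        return ImageVolume(values, self.spacing, self.origin)

    def same_grid(self, other: "ImageVolume | LabelVolume", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, rtol=0, atol=tol)
            and np.allclose(self.origin, other.origin, rtol=0, atol=tol)
        )


@dataclass
class LabelVolume:
    """A per-voxel integer class map sharing a grid with an :class:`ImageVolume`."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValidationError(f"labels must be integer-typed, got {labels.dtype}")
        if labels.ndim != 3:
            raise ValidationError(f"labels must be 3D, got ndim={labels.ndim}")
        self.labels = labels.astype(np.uint8, copy=False)
        self.spacing, self.origin = _check_grid(self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def mask(self, codes) -> np.ndarray:
        """Boolean mask of voxels whose label is in ``codes``."""
        codes = [int(c) for c in np.atleast_1d(codes)]
        return np.isin(self.labels, codes)

    def with_labels(self, labels: np.ndarray) -> "LabelVolume":
        return LabelVolume(labels, self.spacing, self.origin)

    def same_grid(self, other: "ImageVolume | LabelVolume", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, rtol=0, atol=tol)
            and np.allclose(self.origin, other.origin, rtol=0, atol=tol)
        )


def require_same_grid(a, b, what: str = "volumes") -> None:
    """Raise :class:`GridMismatchError` unless ``a`` and ``b`` share a grid."""
    if not a.same_grid(b):
        raise GridMismatchError(
            f"{what} must share one grid: "
            f"shape {a.shape} vs {b.shape}, spacing {a.spacing} vs {b.spacing}, "
            f"origin {a.origin} vs {b.origin}"
        )


def truth_to_seg(truth: LabelVolume) -> LabelVolume:
    """Map ground-truth tissue codes onto the classifier's output codes.

    Cortex and bony callus are both mineralized ("bone" bin); marrow and
    fibrous tissue share one bin; artifacts map to unclassified; pins and
    background map to background.
    """
    lut = np.zeros(max(TRUTH_TO_SEG) + 1, dtype=np.uint8)
    for k, v in TRUTH_TO_SEG.items():
        lut[k] = v
    return truth.with_labels(lut[truth.labels])
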