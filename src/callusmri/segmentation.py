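"""Cortex-normalized intensity thresholding of fracture-callus tissues.

The classification pipeline mirrors the in-vivo MRI protocol it emulates:

1. estimate a mature-cortex reference intensity from diaphyseal cortex
   voxels away from the callus,
2. divide the volume by that reference ("normalized signal intensity"),
3. assign each voxel inside the callus volume of interest (VOI, the axial
   interval between the two inner fixator pins) to one of four bins:

   ============================  =======================
   normalized intensity          class
   ============================  =======================
   [0, 3.4)                      bone (incl. mature cortex)
   [3.4, 5.5)                    bone marrow / fibrous tissue
   [5.5, 6.2]                    cartilage
   > 6.2                         unclassified (artifacts)
   ============================  =======================

The published working ranges (1–3.3, 3.4–5.4, 5.5–6.2) are one-decimal bin
edges; they are implemented as contiguous half-open intervals so that every
voxel receives exactly one class.  Values below 1 fold into the bone bin:
mature cortex anchors the normalization at 1 and noise spreads its values
downward.  Values above 6.2 are left unclassified — susceptibility
artifacts at the fractured cortex ends are far brighter than any tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import (
    ImageVolume,
    LabelVolume,
    SegClass,
    Tissue,
    ValidationError,
    require_same_grid,
)

__all__ = [
    "TissueThresholds",
    "CallusVOI",
    "CentralSlices",
    "estimate_cortex_reference",
    "normalize_intensity",
    "classify_tissues",
    "define_voi_between_inner_pins",
    "select_central_slices",
    "suppress_artifact_components",
]


@dataclass(frozen=True)
class TissueThresholds:
    """Normalized-intensity class boundaries.

    ``bone``, ``fibrous_or_marrow`` and ``cartilage`` are (low, high) pairs
    forming contiguous, strictly increasing intervals; the bone and fibrous
    intervals are half-open at the top, the cartilage interval is closed.
    With ``fold_sub_bone`` (default), values in [0, bone_low) also count as
    bone.
    """

    bone: tuple[float, float] = (1.0, 3.4)
    fibrous_or_marrow: tuple[float, float] = (3.4, 5.5)
    cartilage: tuple[float, float] = (5.5, 6.2)
    fold_sub_bone: bool = True

    def validate(self) -> None:
        for name in ("bone", "fibrous_or_marrow", "cartilage"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"threshold interval {name} must be increasing")
        if self.bone[1] != self.fibrous_or_marrow[0] or self.fibrous_or_marrow[1] != self.cartilage[0]:
            raise ValidationError("threshold intervals must be contiguous")
        if self.bone[0] < 0:
            raise ValidationError("bone lower bound must be >= 0")

    def classify_values(self, values: np.ndarray) -> np.ndarray:
        """Vectorized interval lookup; returns :class:`SegClass` codes."""
        self.validate()
        values = np.asarray(values, dtype=np.float64)
        if np.any(values < 0):
            raise ValidationError("normalized intensities must be non-negative")
        out = np.full(values.shape, int(SegClass.UNCLASSIFIED), dtype=np.uint8)
        out[values < self.fibrous_or_marrow[0]] = SegClass.BONE
        out[(values >= self.fibrous_or_marrow[0]) & (values < self.cartilage[0])] = (
            SegClass.FIBROUS_OR_MARROW
        )
        out[(values >= self.cartilage[0]) & (values <= self.cartilage[1])] = SegClass.CARTILAGE
        if not self.fold_sub_bone:
            out[values < self.bone[0]] = SegClass.UNCLASSIFIED
        return out


@dataclass
class CallusVOI:
    """The callus volume of interest between the two inner fixator pins.

    ``interval`` is the open axial world-coordinate interval (μm) between
    the inner edges of the two inner pins; ``mask`` flags the tissue voxels
    inside it (never pin voxels).
    """

    interval: tuple[float, float]
    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    axis: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not lo < hi:
            raise ValidationError("VOI interval must satisfy lo < hi")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValidationError("VOI mask must be 3D")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def same_grid(self, other) -> bool:
        return (
            self.mask.shape == other.shape
            and np.allclose(self.spacing, other.spacing, rtol=0, atol=1e-9)
            and np.allclose(self.origin, other.origin, rtol=0, atol=1e-9)
        )


def estimate_cortex_reference(
    volume: ImageVolume,
    cortex_mask,
    exclude_interval: tuple[float, float] | None = None,
    axis: int = 0,
) -> float:
    """Median intensity of mature (diaphyseal) cortex.

    ``cortex_mask`` is a boolean array or a :class:`LabelVolume` whose
    cortex code marks cortex voxels.  Voxels whose axial coordinate falls
    inside ``exclude_interval`` (typically the callus VOI, where artifacts
    live) are ignored.  The median makes the estimate robust to residual
    bright outliers.
    """
    if isinstance(cortex_mask, LabelVolume):
        require_same_grid(volume, cortex_mask, "volume and cortex labels")
        mask = cortex_mask.labels == int(Tissue.CORTEX)
    else:
        mask = np.asarray(cortex_mask, dtype=bool)
        if mask.shape != volume.shape:
            raise ValidationError("cortex_mask shape must match the volume")
    if exclude_interval is not None:
        lo, hi = exclude_interval
        coords = volume.axis_coords(axis)
        outside = (coords <= lo) | (coords >= hi)
        shape = [1, 1, 1]
        shape[axis] = len(coords)
        mask = mask & outside.reshape(shape)
    if not mask.any():
        raise ValidationError("cortex mask is empty (after axial exclusion)")
    ref = float(np.median(volume.values[mask]))
    if ref <= 0:
        raise ValidationError("cortex reference intensity must be strictly positive")
    return ref


def normalize_intensity(volume: ImageVolume, reference: float) -> ImageVolume:
    """Divide intensities by the cortex reference (mature cortex maps to ≈1)."""
    if not np.isfinite(reference) or reference <= 0:
        raise ValidationError("reference must be a finite positive scalar")
    return volume.with_values(volume.values / float(reference))


def classify_tissues(
    normalized: ImageVolume,
    thresholds: TissueThresholds,
    voi: CallusVOI,
) -> LabelVolume:
    """Threshold-classify every VOI voxel; voxels outside the VOI are background."""
    if not voi.same_grid(normalized):
        raise ValidationError("VOI grid does not match the normalized volume")
    labels = np.zeros(normalized.shape, dtype=np.uint8)
    labels[voi.mask] = thresholds.classify_values(normalized.values[voi.mask])
    return LabelVolume(labels, normalized.spacing, normalized.origin)


def define_voi_between_inner_pins(
    labels: LabelVolume,
    pin_positions,
    pin_radius_um: float,
    axis: int = 0,
    tissue_mask: np.ndarray | None = None,
    include_cortex: bool = True,
) -> CallusVOI:
    """Build the whole-callus VOI between the two inner pinholes.

    The axial interval runs from the inner edge of the second pin to the
    inner edge of the third (pins sorted by position).  The mask holds every
    non-background, non-pin voxel whose centre lies strictly inside the
    interval; ``include_cortex=False`` additionally drops pre-existing
    cortex (for gap-callus-style analyses).  ``tissue_mask`` overrides the
    label-derived tissue definition.
    """
    pin_positions = sorted(float(p) for p in np.atleast_1d(pin_positions))
    if len(pin_positions) != 4:
        raise ValidationError("exactly four pin positions are required")
    if pin_radius_um < 0:
        raise ValidationError("pin_radius_um must be >= 0")
    p0, p1, p2, p3 = pin_positions
    if not (p0 < p1 < p2 < p3):
        raise ValidationError("inner pins must lie strictly inside the outer pins")
    lo, hi = p1 + pin_radius_um, p2 - pin_radius_um
    if not lo < hi:
        raise ValidationError("degenerate inter-pin interval (inner pins too close)")
    if tissue_mask is not None:
        tissue = np.asarray(tissue_mask, dtype=bool)
        if tissue.shape != labels.shape:
            raise ValidationError("tissue_mask shape must match the label volume")
    else:
        tissue = ~np.isin(labels.labels, [int(Tissue.BACKGROUND), int(Tissue.PIN)])
        if not include_cortex:
            tissue &= labels.labels != int(Tissue.CORTEX)
    tissue = tissue & (labels.labels != int(Tissue.PIN))
    coords = labels.axis_coords(axis)
    inside = (coords > lo) & (coords < hi)
    shape = [1, 1, 1]
    shape[axis] = len(coords)
    mask = tissue & inside.reshape(shape)
    return CallusVOI(
        interval=(lo, hi),
        mask=mask,
        spacing=labels.spacing,
        origin=labels.origin,
        axis=axis,
    )


@dataclass(frozen=True)
class CentralSlices:
    """The two central longitudinal slices through the callus (axis-2 planes)."""

    images: tuple[np.ndarray, np.ndarray]
    indices: tuple[int, int]
    positions_um: tuple[float, float]
    spacing: tuple[float, float]
    single_slice: bool = False


def select_central_slices(voi: CallusVOI, labels: LabelVolume, axis: int = 2) -> CentralSlices:
    """Pick the two slices straddling the callus-mask centroid along ``axis``.

    With centroid coordinate c (continuous voxel units) the slices are
    floor(c) and floor(c)+1, so a centroid exactly on a slice plane selects
    that slice and its upper neighbour.  If the callus spans a single slice
    it is returned twice with ``single_slice=True``.  Returned images are
    label planes masked to the VOI (background elsewhere).
    """
    if axis != 2:
        raise ValidationError("central slices are longitudinal planes normal to axis 2")
    if not voi.same_grid(labels):
        raise ValidationError("VOI grid does not match the label volume")
    counts = voi.mask.sum(axis=(0, 1))
    if counts.sum() == 0:
        raise ValidationError("callus mask is empty")
    occupied = np.nonzero(counts)[0]
    nz = labels.shape[2]
    masked = np.where(voi.mask, labels.labels, 0).astype(np.uint8)
    in_plane = (labels.spacing[0], labels.spacing[1])
    zc = labels.axis_coords(2)
    if len(occupied) == 1:
        k = int(occupied[0])
        warnings.warn("callus thinner than two slices; returning the single slice twice")
        return CentralSlices(
            images=(masked[:, :, k], masked[:, :, k]),
            indices=(k, k),
            positions_um=(float(zc[k]), float(zc[k])),
            spacing=in_plane,
            single_slice=True,
        )
    centroid = float((counts * np.arange(nz)).sum() / counts.sum())
    k = int(np.floor(centroid))
    k = min(max(k, 0), nz - 2)
    return CentralSlices(
        images=(masked[:, :, k], masked[:, :, k + 1]),
        indices=(k, k + 1),
        positions_um=(float(zc[k]), float(zc[k + 1])),
        spacing=in_plane,
    )


def suppress_artifact_components(
    labels: LabelVolume,
    min_volume_um3: float,
    cortex_end_mask: np.ndarray,
) -> LabelVolume:
    """Relabel small cartilage components at the cortex ends as unclassified.

    Susceptibility artifacts that leak into the cartilage bin form small,
    very bright islands at the fractured cortex ends.  Cartilage-labeled
    26-connected components smaller than ``min_volume_um3`` that touch
    ``cortex_end_mask`` (within one voxel) are reassigned to the
    unclassified class; everything else is untouched.
    """
    if min_volume_um3 < 0:
        raise ValidationError("min_volume_um3 must be >= 0")
    cortex_end_mask = np.asarray(cortex_end_mask, dtype=bool)
    if cortex_end_mask.shape != labels.shape:
        raise ValidationError("cortex_end_mask shape must match the label volume")
    out = labels.labels.copy()
    if min_volume_um3 == 0:
        return labels.with_labels(out)
    cart = out == int(SegClass.CARTILAGE)
    structure = np.ones((3, 3, 3), dtype=bool)
    comps, n = ndimage.label(cart, structure=structure)
    if n == 0:
        return labels.with_labels(out)
    touch_zone = ndimage.binary_dilation(cortex_end_mask, structure=structure)
    touching = np.unique(comps[touch_zone & cart])
    sizes = ndimage.sum_labels(np.ones_like(comps), comps, index=np.arange(1, n + 1))
    voxvol = labels.voxel_volume_um3
    for comp_id in touching:
        if comp_id == 0:
            continue
        if sizes[comp_id - 1] * voxvol < min_volume_um3:
            out[comps == comp_id] = SegClass.UNCLASSIFIED
    return labels.with_labels(out)
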