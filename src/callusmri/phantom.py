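"""Seeded synthetic femur-osteotomy phantoms.

Each phantom emulates one mouse femur with an externally fixated mid-shaft
osteotomy at a chosen healing stage: a matched in-vivo-MRI-like volume
(52×52×350 μm voxels by default), an ex-vivo-μCT-like mineral-density volume
(8 μm isotropic), a ground-truth tissue label map on each grid, and two
pseudo-histology sections registered to the two central MRI slices.

Geometry model
--------------
The femur shaft runs along axis 0 (x).  The cortex is a cylindrical shell
interrupted by the osteotomy gap; marrow fills the medullary canal.  The
fracture callus is a fusiform (spindle-shaped) body of revolution spanning
the interval between the inner fixator pins.  Within the callus, tissue
compartments follow the healing stage:

* cartilage forms a central ellipsoidal lobe around the gap (large at day
  10, shrinking by day 14, nearly absent by day 21),
* woven bone forms a peripheral shell that thickens and spreads inward with
  healing (thin at day 10, a ring at day 14, pervasive by day 21),
* fibrous tissue fills the remainder.

Compartment boundaries (the bone shell's inner surface and the cartilage
lobe's extent) are solved in continuum coordinates so that the callus
class-volume fractions hit ``target_fractions``; the same physical geometry
is then rasterized independently on the μCT and MRI grids, so the coarse
grid carries a genuine voxelization error.

Signal model
------------
MRI voxel intensities are drawn per tissue class from disjoint
cortex-normalized intervals (cortex darkest, then bony callus, then
marrow/fibrous, cartilage brightest among tissues, susceptibility artifacts
brighter still), scaled by a raw cortex reference intensity, optionally
multiplied by a linear coil-sensitivity ramp, and corrupted by Rician
(magnitude-image) noise.  μCT voxels carry mineral densities that straddle
the 642 mg HA/cm³ mineralization threshold with margin: high density in
cortex and bony callus, low density elsewhere.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .volume import (
    ImageVolume,
    LabelVolume,
    Tissue,
    ValidationError,
    require_same_grid,
)

__all__ = [
    "DAY_TARGET_FRACTIONS",
    "PhantomSpec",
    "TissueIntensityModel",
    "PhantomBundle",
    "HistologySection",
    "generate_phantom",
    "apply_coil_gradient",
    "apply_rician_noise",
    "insert_susceptibility_artifacts",
    "resample_to_mri_grid",
    "render_histology_sections",
    "cortex_end_mask",
    "solve_class_boundaries",
    "rasterize_truth",
]

#: Default callus composition per healing day (volume fractions).  Cartilage
#: peaks early and is nearly absent by day 21; bone spreads inward by day 21.
DAY_TARGET_FRACTIONS: dict[int, dict[str, float]] = {
    10: {"bone": 0.10, "cartilage": 0.16, "fibrous": 0.74},
    14: {"bone": 0.15, "cartilage": 0.18, "fibrous": 0.67},
    21: {"bone": 0.45, "cartilage": 0.03, "fibrous": 0.52},
}

_VALID_DAYS = (10, 14, 21)
_MIN_DENSITY_MINERALIZED = 700.0  # mg HA/cm³, straddles 642 with margin
_MAX_DENSITY_MINERALIZED = 1200.0
_MAX_DENSITY_SOFT = 300.0


@dataclass
class PhantomSpec:
    """Geometry, imaging and corruption parameters of one phantom.

    All lengths are μm.  ``pin_positions`` are the four fixator-pin axial
    (x) coordinates; the osteotomy gap must lie strictly between the inner
    edges of the two inner pins.  ``target_fractions`` are callus volume
    fractions per class (bone / cartilage / fibrous, summing to ≤ 1); when
    omitted they default to the healing-day values in
    :data:`DAY_TARGET_FRACTIONS`.
    """

    healing_day: int = 10
    cortex_outer_radius: float = 800.0
    cortex_thickness: float = 200.0
    gap_width: float = 500.0
    callus_max_radius: float = 1400.0
    target_fractions: dict[str, float] | None = None
    pin_positions: tuple[float, float, float, float] | None = None
    pin_radius: float = 150.0
    noise_sigma: float = 0.05
    coil_gradient_amplitude: float = 0.1
    artifact_count: int = 4
    artifact_radius: float = 150.0
    histology_jitter_sigma: float = 15.0
    mri_spacing: tuple[float, float, float] = (52.0, 52.0, 350.0)
    mri_shape: tuple[int, int, int] = (128, 128, 22)
    uct_spacing: tuple[float, float, float] = (8.0, 8.0, 8.0)
    #: world offset (μm) of the anatomy relative to the grid centre —
    #: emulates animal positioning; sub-voxel offsets decorrelate the
    #: voxelization error between specimens.
    center_offset_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_fractions is None:
            if self.healing_day in DAY_TARGET_FRACTIONS:
                self.target_fractions = dict(DAY_TARGET_FRACTIONS[self.healing_day])
        if self.pin_positions is None:
            xc = self.axial_center
            self.pin_positions = (xc - 2800.0, xc - 1600.0, xc + 1600.0, xc + 2800.0)
        self.pin_positions = tuple(float(p) for p in self.pin_positions)
        self.mri_spacing = tuple(float(s) for s in self.mri_spacing)
        self.mri_shape = tuple(int(n) for n in self.mri_shape)
        self.uct_spacing = tuple(float(s) for s in self.uct_spacing)
        self.center_offset_um = tuple(float(o) for o in self.center_offset_um)

    # --- derived geometry -------------------------------------------------
    @property
    def x_extent(self) -> float:
        """World x coordinate of the last MRI voxel centre (origin at 0)."""
        return (self.mri_shape[0] - 1) * self.mri_spacing[0]

    @property
    def axial_center(self) -> float:
        return self.x_extent / 2.0 + self.center_offset_um[0]

    @property
    def transverse_center(self) -> tuple[float, float]:
        return (
            (self.mri_shape[1] - 1) * self.mri_spacing[1] / 2.0 + self.center_offset_um[1],
            (self.mri_shape[2] - 1) * self.mri_spacing[2] / 2.0 + self.center_offset_um[2],
        )

    @property
    def inner_pin_interval(self) -> tuple[float, float]:
        """Open axial interval between the inner edges of the inner pins."""
        p = sorted(self.pin_positions)
        return (p[1] + self.pin_radius, p[2] - self.pin_radius)

    @property
    def callus_half_length(self) -> float:
        lo, hi = self.inner_pin_interval
        return 0.95 * (hi - lo) / 2.0

    @property
    def cortex_inner_radius(self) -> float:
        return self.cortex_outer_radius - self.cortex_thickness

    # ----------------------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ValidationError` naming the first violated invariant."""
        if self.healing_day not in _VALID_DAYS:
            raise ValidationError(f"healing_day must be one of {_VALID_DAYS}, got {self.healing_day}")
        for name in ("cortex_outer_radius", "cortex_thickness", "gap_width",
                     "callus_max_radius", "pin_radius"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.cortex_thickness >= self.cortex_outer_radius:
            raise ValidationError("cortex_thickness must be smaller than cortex_outer_radius")
        if self.callus_max_radius <= self.cortex_outer_radius:
            raise ValidationError("callus_max_radius must exceed cortex_outer_radius")
        if self.target_fractions is None:
            raise ValidationError("target_fractions required for healing_day outside defaults")
        extra = set(self.target_fractions) - {"bone", "cartilage", "fibrous"}
        if extra:
            raise ValidationError(f"unknown target_fractions keys: {sorted(extra)}")
        fracs = {k: float(self.target_fractions.get(k, 0.0)) for k in ("bone", "cartilage", "fibrous")}
        for k, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"target_fractions[{k!r}] must be in [0, 1], got {v}")
        if sum(fracs.values()) > 1.0 + 1e-9:
            raise ValidationError("target_fractions must sum to <= 1")
        if len(self.pin_positions) != 4:
            raise ValidationError("pin_positions must hold exactly four axial coordinates")
        p = sorted(self.pin_positions)
        if len(set(p)) != 4:
            raise ValidationError("pin_positions must be distinct")
        lo, hi = self.inner_pin_interval
        if lo >= hi:
            raise ValidationError("inner pins too close: degenerate inter-pin interval")
        xc = self.axial_center
        if not (lo < xc - self.gap_width / 2 and xc + self.gap_width / 2 < hi):
            raise ValidationError("osteotomy gap must lie strictly between the inner pins")
        if p[0] < 0 or p[3] > self.x_extent:
            raise ValidationError("pin_positions must lie inside the MRI volume extent")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if not 0.0 <= self.coil_gradient_amplitude < 0.5:
            raise ValidationError("coil_gradient_amplitude must be in [0, 0.5)")
        if not 0 <= self.artifact_count <= 4:
            raise ValidationError("artifact_count must be in 0..4 (four cortex-end corners)")
        if self.artifact_radius >= self.gap_width / 2:
            raise ValidationError("artifact_radius must be smaller than gap_width/2")
        if self.histology_jitter_sigma < 0:
            raise ValidationError("histology_jitter_sigma must be >= 0")
        if any(s <= 0 for s in self.mri_spacing) or any(s <= 0 for s in self.uct_spacing):
            raise ValidationError("spacings must be strictly positive")
        if any(n < 2 for n in self.mri_shape):
            raise ValidationError("mri_shape must be >= 2 per axis")
        cy, cz = self.transverse_center
        ty = (self.mri_shape[1] - 1) * self.mri_spacing[1]
        tz = (self.mri_shape[2] - 1) * self.mri_spacing[2]
        if self.callus_max_radius > min(cy, ty - cy, cz, tz - cz):
            raise ValidationError("callus_max_radius does not fit inside the transverse field of view")


@dataclass(frozen=True)
class TissueIntensityModel:
    """Per-class cortex-normalized intensity sampling intervals.

    Intervals are disjoint and strictly ordered (cortex < bony callus <
    marrow/fibrous < cartilage < artifact) and sit inside the corresponding
    classification bins with margin, so a noise-free phantom is exactly
    recoverable by thresholding.  ``cortex_reference_raw`` scales normalized
    units to raw scanner units.
    """

    cortex: tuple[float, float] = (0.98, 1.02)
    bone_callus: tuple[float, float] = (1.05, 3.35)
    fibrous: tuple[float, float] = (3.45, 5.45)
    marrow: tuple[float, float] = (3.45, 5.45)
    cartilage: tuple[float, float] = (5.52, 6.18)
    artifact: tuple[float, float] = (6.8, 7.5)
    background: tuple[float, float] = (2.5, 4.5)
    pin: tuple[float, float] = (0.0, 0.15)
    cortex_reference_raw: float = 50.0

    def interval_for(self, tissue: Tissue) -> tuple[float, float]:
        return {
            Tissue.BACKGROUND: self.background,
            Tissue.CORTEX: self.cortex,
            Tissue.MARROW: self.marrow,
            Tissue.BONE_CALLUS: self.bone_callus,
            Tissue.CARTILAGE: self.cartilage,
            Tissue.FIBROUS: self.fibrous,
            Tissue.ARTIFACT: self.artifact,
            Tissue.PIN: self.pin,
        }[tissue]

    def validate(self) -> None:
        if self.cortex_reference_raw <= 0:
            raise ValidationError("cortex_reference_raw must be > 0")
        for name in ("cortex", "bone_callus", "fibrous", "marrow", "cartilage",
                     "artifact", "background", "pin"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 <= lo <= hi):
                raise ValidationError(f"intensity interval {name} must satisfy 0 <= lo <= hi")
        chain = [self.cortex, self.bone_callus, self.fibrous, self.cartilage, self.artifact]
        names = ["cortex", "bone_callus", "fibrous", "cartilage", "artifact"]
        for (lo_a, hi_a), (lo_b, hi_b), na, nb in zip(chain, chain[1:], names, names[1:]):
            if hi_a >= lo_b:
                raise ValidationError(f"intensity intervals must be ordered without overlap: {na} vs {nb}")
        if self.marrow != self.fibrous:
            # marrow and fibrous tissue are iso-intense by construction; allow
            # distinct intervals only if marrow also sits between bone and cartilage
            if not (self.bone_callus[1] < self.marrow[0] and self.marrow[1] < self.cartilage[0]):
                raise ValidationError("marrow interval must lie between bone_callus and cartilage")


@dataclass(frozen=True)
class HistologySection:
    """A 2D pseudo-histology label image (x, y) at a given slice plane z."""

    labels: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float]
    z_um: float


@dataclass
class PhantomBundle:
    """One phantom's matched modalities and ground truth."""

    mri: ImageVolume
    truth_mri_grid: LabelVolume
    uct: ImageVolume | None
    truth: LabelVolume | None
    histology_sections: list[HistologySection] | None
    spec: PhantomSpec
    model: TissueIntensityModel


# ---------------------------------------------------------------------------
# continuum geometry
# ---------------------------------------------------------------------------

def _callus_radial_bounds(spec: PhantomSpec, x: np.ndarray):
    """Per-axial-position radial interval (r0, r1] occupied by callus."""
    xc = spec.axial_center
    L = spec.callus_half_length
    s = (x - xc) / L
    r1 = spec.callus_max_radius * np.sqrt(np.clip(1.0 - s * s, 0.0, None))
    in_gap = np.abs(x - xc) < spec.gap_width / 2
    # inside the gap the callus fills the whole cross-section (r >= 0);
    # elsewhere it is periosteal, outside the old cortex
    r0 = np.where(in_gap, -1.0, spec.cortex_outer_radius)
    r1 = np.where(np.abs(s) < 1.0, r1, 0.0)
    return r0, r1


def _cartilage_radius(spec: PhantomSpec, x: np.ndarray, d: float) -> np.ndarray:
    """Radial extent of the central cartilage lobe at scale ``d``."""
    a = 0.8 * spec.callus_half_length
    b = 0.8 * spec.callus_max_radius
    s = (x - spec.axial_center) / a
    return b * np.sqrt(np.clip(d * d - s * s, 0.0, None))


def _class_areas(spec: PhantomSpec, x: np.ndarray, u: float, d: float):
    """Cross-sectional areas (callus, bone, cartilage) at axial positions x."""
    r0, r1 = _callus_radial_bounds(spec, x)
    r0c = np.clip(r0, 0.0, None)
    has = r1 > r0c
    a_callus = np.where(has, np.pi * (r1**2 - r0c**2), 0.0)
    # peripheral bone shell: r >= u * r1
    rb = np.clip(u * r1, r0c, r1)
    a_bone = np.where(has, np.pi * (r1**2 - rb**2), 0.0)
    # central cartilage lobe inside the non-bone part: r0 < r <= min(rc, rb)
    rc = np.minimum(_cartilage_radius(spec, x, d), rb)
    a_cart = np.where(has & (rc > r0c), np.pi * (np.clip(rc, r0c, None) ** 2 - r0c**2), 0.0)
    return a_callus, a_bone, a_cart


def _fractions(spec: PhantomSpec, u: float, d: float, n: int = 2001):
    xc, L = spec.axial_center, spec.callus_half_length
    edges = np.linspace(xc - L, xc + L, n + 1)
    x = 0.5 * (edges[:-1] + edges[1:])
    a_callus, a_bone, a_cart = _class_areas(spec, x, u, d)
    v = a_callus.sum()
    return a_bone.sum() / v, a_cart.sum() / v


@dataclass(frozen=True)
class ClassBoundaries:
    """Solved compartment boundaries: bone shell at u*r1, cartilage lobe scale d."""

    u: float
    d: float


def solve_class_boundaries(spec: PhantomSpec) -> ClassBoundaries:
    """Solve the bone-shell and cartilage-lobe boundaries for the target fractions.

    Uses 1D quadrature over the callus axis (the geometry is a body of
    revolution) and bisection; raises :class:`ValidationError` if the
    cartilage target cannot be reached inside the non-bone compartment.
    """
    spec.validate()
    fb = float(spec.target_fractions.get("bone", 0.0))
    fc = float(spec.target_fractions.get("cartilage", 0.0))
    if fb <= 1e-12:
        u = 1.0
    elif fb >= 1.0 - 1e-12:
        u = 0.0
    else:
        u = brentq(lambda uu: _fractions(spec, uu, 0.0)[0] - fb, 0.0, 1.0, xtol=1e-12)
    if fc <= 1e-12:
        d = 0.0
    else:
        d_hi = 1.0
        while _fractions(spec, u, d_hi)[1] < fc:
            d_hi *= 2.0
            if d_hi > 64.0:
                raise ValidationError(
                    "cartilage target_fraction unreachable inside the non-bone callus"
                )
        d = brentq(lambda dd: _fractions(spec, u, dd)[1] - fc, 0.0, d_hi, xtol=1e-12)
    return ClassBoundaries(u=float(u), d=float(d))


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize_truth(
    spec: PhantomSpec,
    boundaries: ClassBoundaries,
    spacing: tuple[float, float, float],
    shape: tuple[int, int, int],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    chunk: int = 64,
) -> LabelVolume:
    """Rasterize the continuum phantom geometry onto an arbitrary grid."""
    nx, ny, nz = shape
    sx, sy, sz = spacing
    y0, z0 = spec.transverse_center
    xc = spec.axial_center
    x = origin[0] + np.arange(nx) * sx
    y = origin[1] + np.arange(ny) * sy
    z = origin[2] + np.arange(nz) * sz
    r = np.hypot((y - y0)[:, None], (z - z0)[None, :])  # (ny, nz)

    in_gap = np.abs(x - xc) < spec.gap_width / 2
    r0, r1 = _callus_radial_bounds(spec, x)
    rb = np.clip(boundaries.u * r1, np.clip(r0, 0.0, None), r1)
    rc = np.minimum(_cartilage_radius(spec, x, boundaries.d), rb)

    labels = np.zeros(shape, dtype=np.uint8)
    Rco, Rci = spec.cortex_outer_radius, spec.cortex_inner_radius
    for i0 in range(0, nx, chunk):
        i1 = min(i0 + chunk, nx)
        gap_c = in_gap[i0:i1, None, None]
        rr = r[None, :, :]
        lab = np.zeros((i1 - i0, ny, nz), dtype=np.uint8)
        # pre-existing bone structure outside the gap
        lab[(~gap_c) & (rr <= Rci)] = Tissue.MARROW
        lab[(~gap_c) & (rr <= Rco) & (rr > Rci)] = Tissue.CORTEX
        # callus compartments
        cal = (rr > r0[i0:i1, None, None]) & (rr <= r1[i0:i1, None, None])
        lab[cal] = Tissue.FIBROUS
        lab[cal & (rr <= rc[i0:i1, None, None])] = Tissue.CARTILAGE
        if boundaries.u < 1.0:
            lab[cal & (rr >= rb[i0:i1, None, None])] = Tissue.BONE_CALLUS
        labels[i0:i1] = lab
    # fixator pins: cylinders along y through the shaft axis
    zz = z - z0
    span = np.abs(y - y0) <= Rco + 1500.0
    for xp in spec.pin_positions:
        hole = (x - xp)[:, None] ** 2 + zz[None, :] ** 2 <= spec.pin_radius**2  # (nx, nz)
        if hole.any():
            labels[hole[:, None, :] & span[None, :, None]] = Tissue.PIN
    return LabelVolume(labels, spacing, origin)


# ---------------------------------------------------------------------------
# corruption operators
# ---------------------------------------------------------------------------

def apply_coil_gradient(volume: ImageVolume, amplitude: float, axis: int = 0) -> ImageVolume:
    """Multiply intensities by a linear receive-sensitivity ramp 1∓amplitude → 1±amplitude.

    ``amplitude`` must lie in [0, 0.5) so the gain stays strictly positive.
    """
    if not 0.0 <= amplitude < 0.5:
        raise ValidationError("coil gradient amplitude must be in [0, 0.5)")
    if axis not in (0, 1, 2):
        raise ValidationError("axis must be 0, 1 or 2")
    n = volume.shape[axis]
    ramp = np.linspace(1.0 - amplitude, 1.0 + amplitude, n)
    shape = [1, 1, 1]
    shape[axis] = n
    return volume.with_values(volume.values * ramp.reshape(shape))


def apply_rician_noise(volume: ImageVolume, sigma: float, seed) -> ImageVolume:
    """Corrupt a magnitude image with Rician noise of scale ``sigma`` (raw units).

    Each voxel v becomes sqrt((v + n1)² + n2²) with n1, n2 ~ N(0, sigma²);
    sigma = 0 returns the input unchanged.  ``seed`` may be an int or a
    :class:`numpy.random.Generator`.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if sigma == 0:
        return volume.with_values(volume.values.copy())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, volume.shape)
    n2 = rng.normal(0.0, sigma, volume.shape)
    return volume.with_values(np.hypot(volume.values + n1, n2))


def _artifact_centers(spec: PhantomSpec) -> list[tuple[float, float, float]]:
    """The four cortex-end corners adjacent to the osteotomy gap."""
    xc = spec.axial_center
    y0, z0 = spec.transverse_center
    ry = spec.cortex_outer_radius - spec.cortex_thickness / 2
    centers = []
    for dx in (-1.0, 1.0):
        for dy in (-1.0, 1.0):
            centers.append((xc + dx * spec.gap_width / 2, y0 + dy * ry, z0))
    return centers


def insert_susceptibility_artifacts(
    volume: ImageVolume,
    truth: LabelVolume,
    spec: PhantomSpec,
    model: TissueIntensityModel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ImageVolume, LabelVolume]:
    """Place bright blobs at the fractured cortex ends and relabel truth there.

    Blobs emulate susceptibility artifacts at the bone/soft-tissue transition:
    ellipsoids of ``artifact_radius`` (inflated to at least half a voxel per
    axis so they survive anisotropic sampling) whose intensity is drawn above
    the brightest tissue bin.  The corresponding truth voxels are relabeled
    :attr:`Tissue.ARTIFACT`.
    """
    model = model or TissueIntensityModel()
    require_same_grid(volume, truth, "volume and truth")
    if spec.artifact_radius >= spec.gap_width / 2:
        raise ValidationError("artifact_radius must be smaller than gap_width/2")
    if spec.artifact_count == 0:
        return volume.with_values(volume.values.copy()), truth.with_labels(truth.labels.copy())
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    semi = tuple(max(spec.artifact_radius, s / 2) for s in volume.spacing)
    vals = volume.values.copy()
    labs = truth.labels.copy()
    coords = [volume.axis_coords(a) for a in range(3)]
    lo_ext = [c[0] for c in coords]
    hi_ext = [c[-1] for c in coords]
    for center in _artifact_centers(spec)[: spec.artifact_count]:
        # snap to the nearest voxel centre so the blob survives coarse
        # anisotropic sampling (sub-voxel position is unresolvable anyway)
        cx, cy, cz = (
            coords[a][int(np.argmin(np.abs(coords[a] - c)))]
            for a, c in enumerate(center)
        )
        for c, s, lo, hi in zip((cx, cy, cz), semi, lo_ext, hi_ext):
            if c - s < lo - 1e-9 or c + s > hi + 1e-9:
                raise ValidationError("artifact blob would exceed the volume bounds")
        m = (
            ((coords[0] - cx) / semi[0])[:, None, None] ** 2
            + ((coords[1] - cy) / semi[1])[None, :, None] ** 2
            + ((coords[2] - cz) / semi[2])[None, None, :] ** 2
        ) <= 1.0
        lo_i, hi_i = model.artifact
        vals[m] = rng.uniform(lo_i, hi_i, int(m.sum())) * model.cortex_reference_raw
        labs[m] = Tissue.ARTIFACT
    return volume.with_values(vals), truth.with_labels(labs)


# ---------------------------------------------------------------------------
# resampling / sections
# ---------------------------------------------------------------------------

#: Tie-break priority for majority-vote downsampling (first wins ties).
_RESAMPLE_PRIORITY = (
    Tissue.BONE_CALLUS,
    Tissue.CARTILAGE,
    Tissue.FIBROUS,
    Tissue.CORTEX,
    Tissue.MARROW,
    Tissue.ARTIFACT,
    Tissue.PIN,
    Tissue.BACKGROUND,
)


def resample_to_mri_grid(
    truth: LabelVolume, mri_spacing: tuple[float, float, float]
) -> LabelVolume:
    """Majority-vote downsample of a fine label grid onto a coarser grid.

    Requires each coarse spacing to be an integer multiple of the fine
    spacing (tolerance 1%); ties are broken by a fixed class priority
    (bone > cartilage > fibrous > ... > background).  Trailing fine voxels
    that do not fill a whole coarse voxel are dropped.
    """
    mri_spacing = tuple(float(s) for s in mri_spacing)
    factors = []
    for sm, st in zip(mri_spacing, truth.spacing):
        f = sm / st
        k = int(round(f))
        if k < 1 or abs(f - k) > 0.01 * f:
            raise ValidationError(
                f"mri spacing {sm} is not an integer multiple of truth spacing {st}"
            )
        factors.append(k)
    kx, ky, kz = factors
    nx, ny, nz = (truth.shape[a] // factors[a] for a in range(3))
    if nx == 0 or ny == 0 or nz == 0:
        raise ValidationError("truth volume smaller than one coarse voxel")
    block = truth.labels[: nx * kx, : ny * ky, : nz * kz].reshape(nx, kx, ny, ky, nz, kz)
    best_count = np.zeros((nx, ny, nz), dtype=np.int64)
    out = np.zeros((nx, ny, nz), dtype=np.uint8)
    for tissue in _RESAMPLE_PRIORITY:
        count = (block == int(tissue)).sum(axis=(1, 3, 5))
        take = count > best_count
        out[take] = int(tissue)
        best_count = np.maximum(best_count, count)
    origin = tuple(
        truth.origin[a] + (factors[a] - 1) / 2.0 * truth.spacing[a] for a in range(3)
    )
    return LabelVolume(out, mri_spacing, origin)


def render_histology_sections(
    truth: LabelVolume,
    slice_positions: tuple[float, float],
    jitter_sigma: float = 0.0,
    seed=0,
    in_plane_spacing: float = 7.0,
    smoothing_px: float = 4.0,
) -> list[HistologySection]:
    """Extract longitudinal pseudo-histology sections at the given z planes.

    Each section is the truth label plane nearest the requested world z,
    resampled in-plane to ``in_plane_spacing`` μm (nearest neighbour), with
    class boundaries perturbed by a smooth random displacement field of
    r.m.s. amplitude ``jitter_sigma`` μm, emulating sectioning and staining
    distortion.  ``jitter_sigma = 0`` returns exact slices.
    """
    if jitter_sigma < 0:
        raise ValidationError("jitter_sigma must be >= 0")
    if in_plane_spacing <= 0:
        raise ValidationError("in_plane_spacing must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    zc = truth.axis_coords(2)
    sections = []
    for z in slice_positions:
        if z < zc[0] - truth.spacing[2] / 2 or z > zc[-1] + truth.spacing[2] / 2:
            raise ValidationError(f"slice position {z} μm lies outside the truth volume")
        k = int(np.argmin(np.abs(zc - z)))
        plane = truth.labels[:, :, k]
        # nearest-neighbour in-plane resample onto the section grid
        xi = np.arange(int(np.floor((truth.shape[0] - 1) * truth.spacing[0] / in_plane_spacing)) + 1)
        yi = np.arange(int(np.floor((truth.shape[1] - 1) * truth.spacing[1] / in_plane_spacing)) + 1)
        src_x = np.rint(xi * in_plane_spacing / truth.spacing[0]).astype(int)
        src_y = np.rint(yi * in_plane_spacing / truth.spacing[1]).astype(int)
        sec = plane[np.ix_(src_x, src_y)]
        if jitter_sigma > 0:
            disp = rng.standard_normal((2,) + sec.shape)
            disp = ndimage.gaussian_filter(disp, sigma=(0, smoothing_px, smoothing_px))
            for c in range(2):
                sd = disp[c].std()
                if sd > 0:
                    disp[c] *= (jitter_sigma / in_plane_spacing) / sd
            ii, jj = np.meshgrid(
                np.arange(sec.shape[0], dtype=float),
                np.arange(sec.shape[1], dtype=float),
                indexing="ij",
            )
            sec = ndimage.map_coordinates(
                sec, [ii + disp[0], jj + disp[1]], order=0, mode="nearest"
            )
        sections.append(
            HistologySection(
                labels=sec.astype(np.uint8),
                spacing=(in_plane_spacing, in_plane_spacing),
                origin=(truth.origin[0], truth.origin[1]),
                z_um=float(zc[k]),
            )
        )
    return sections


def cortex_end_mask(truth: LabelVolume, spec: PhantomSpec, margin_um: float = 250.0) -> np.ndarray:
    """Boolean mask of cortex voxels within ``margin_um`` of the osteotomy edges."""
    xc = spec.axial_center
    x = truth.axis_coords(0)
    near = (np.abs(x - (xc - spec.gap_width / 2)) <= margin_um) | (
        np.abs(x - (xc + spec.gap_width / 2)) <= margin_um
    )
    return (truth.labels == int(Tissue.CORTEX)) & near[:, None, None]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _sample_intensities(
    truth: LabelVolume, model: TissueIntensityModel, rng: np.random.Generator
) -> ImageVolume:
    out = np.empty(truth.shape, dtype=np.float64)
    ref = model.cortex_reference_raw
    for tissue in Tissue:
        m = truth.labels == int(tissue)
        n = int(m.sum())
        if n == 0:
            continue
        lo, hi = model.interval_for(tissue)
        out[m] = rng.uniform(lo, hi, n) * ref
    return ImageVolume(out, truth.spacing, truth.origin)


def _uct_grid(spec: PhantomSpec):
    p = sorted(spec.pin_positions)
    y0, z0 = spec.transverse_center
    margin = 300.0
    rext = spec.callus_max_radius + 200.0
    lo = (p[1] - margin, y0 - rext, z0 - rext)
    hi = (p[2] + margin, y0 + rext, z0 + rext)
    shape = tuple(
        int(np.floor((h - l) / s)) + 1 for l, h, s in zip(lo, hi, spec.uct_spacing)
    )
    return spec.uct_spacing, shape, lo


def central_slice_positions(spec: PhantomSpec) -> tuple[float, float]:
    """World z of the two MRI slices straddling the volume centre."""
    nz, sz = spec.mri_shape[2], spec.mri_spacing[2]
    k = (nz - 1) // 2
    return (k * sz, (k + 1) * sz)


def generate_phantom(
    spec: PhantomSpec,
    model: TissueIntensityModel | None = None,
    modalities: tuple[str, ...] = ("mri", "uct", "histology"),
) -> PhantomBundle:
    """Generate one seeded phantom bundle.

    ``modalities`` selects which outputs to synthesize; the MRI volume and
    its ground-truth label map are always produced.  Identical
    (spec, model) inputs yield bit-identical bundles.
    """
    model = model or TissueIntensityModel()
    spec.validate()
    model.validate()
    unknown = set(modalities) - {"mri", "uct", "histology"}
    if unknown:
        raise ValidationError(f"unknown modalities: {sorted(unknown)}")
    boundaries = solve_class_boundaries(spec)
    ss = np.random.SeedSequence(spec.seed)
    s_mri, s_uct, s_art, s_noise, s_hist = ss.spawn(5)

    truth_mri = rasterize_truth(spec, boundaries, spec.mri_spacing, spec.mri_shape)
    mri = _sample_intensities(truth_mri, model, np.random.default_rng(s_mri))
    if spec.coil_gradient_amplitude > 0:
        mri = apply_coil_gradient(mri, spec.coil_gradient_amplitude, axis=0)
    if spec.artifact_count > 0:
        mri, truth_mri = insert_susceptibility_artifacts(
            mri, truth_mri, spec, model, np.random.default_rng(s_art)
        )
    if spec.noise_sigma > 0:
        mri = apply_rician_noise(
            mri, spec.noise_sigma * model.cortex_reference_raw, np.random.default_rng(s_noise)
        )

    truth = uct = sections = None
    if "uct" in modalities or "histology" in modalities:
        spacing, shape, origin = _uct_grid(spec)
        truth = rasterize_truth(spec, boundaries, spacing, shape, origin)
    if "uct" in modalities:
        rng_u = np.random.default_rng(s_uct)
        dens = rng_u.uniform(0.0, _MAX_DENSITY_SOFT, truth.shape)
        mineral = truth.mask([Tissue.CORTEX, Tissue.BONE_CALLUS])
        dens[mineral] = rng_u.uniform(
            _MIN_DENSITY_MINERALIZED, _MAX_DENSITY_MINERALIZED, int(mineral.sum())
        )
        pins = truth.labels == int(Tissue.PIN)
        dens[pins] = rng_u.uniform(0.0, 50.0, int(pins.sum()))
        uct = ImageVolume(dens, truth.spacing, truth.origin)
    if "histology" in modalities:
        sections = render_histology_sections(
            truth,
            central_slice_positions(spec),
            jitter_sigma=spec.histology_jitter_sigma,
            seed=np.random.default_rng(s_hist),
        )
    return PhantomBundle(
        mri=mri,
        truth_mri_grid=truth_mri,
        uct=uct,
        truth=truth,
        histology_sections=sections,
        spec=spec,
        model=model,
    )
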