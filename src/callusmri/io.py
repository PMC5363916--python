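"""Volume, label, configuration and report I/O.

Volumes travel as NIfTI-1 (spacing recorded in the header in mm, i.e.
μm × 10⁻³); label maps additionally carry a JSON class-code table alongside
(``<path>.codes.json``).  NIfTI headers hold spacings as float32, so the
exact float64 grid (spacing and origin in μm) is also embedded in a JSON
header extension and restored verbatim on read — a write→read round-trip
preserves voxels, spacing and origin bit-exactly.  Multi-page TIFF export
is available for viewers that prefer stacks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .phantom import PhantomSpec, TissueIntensityModel
from .quantify import UCT_BONE_THRESHOLD_MG_HA_CM3
from .segmentation import TissueThresholds
from .volume import (
    ImageVolume,
    LabelVolume,
    SEG_CODE_TABLE,
    TISSUE_CODE_TABLE,
    ValidationError,
)

__all__ = [
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "write_volume_tiff",
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
]

_GRID_EXT_MARKER = "callusmri-grid:"
_COMMENT_ECODE = 6


def _grid_extension(spacing, origin) -> nib.nifti1.Nifti1Extension:
    payload = _GRID_EXT_MARKER + json.dumps(
        {"spacing_um": list(spacing), "origin_um": list(origin)}
    )
    return nib.nifti1.Nifti1Extension(_COMMENT_ECODE, payload.encode())


def _grid_from_header(img) -> tuple[tuple, tuple] | None:
    for ext in img.header.extensions:
        try:
            content = ext.get_content()
            text = content.decode() if isinstance(content, bytes) else str(content)
        except Exception:
            continue
        if text.startswith(_GRID_EXT_MARKER):
            d = json.loads(text[len(_GRID_EXT_MARKER):])
            return tuple(d["spacing_um"]), tuple(d["origin_um"])
    return None


def _nifti_for(array: np.ndarray, spacing_um, origin_um) -> nib.Nifti1Image:
    affine = np.eye(4)
    for a in range(3):
        affine[a, a] = spacing_um[a] * 1e-3
        affine[a, 3] = origin_um[a] * 1e-3
    img = nib.Nifti1Image(array, affine)
    img.header.set_zooms(tuple(s * 1e-3 for s in spacing_um))
    img.header.set_xyzt_units(xyz="mm")
    img.header.extensions.append(_grid_extension(spacing_um, origin_um))
    return img


def _load_nifti(path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    grid = _grid_from_header(img)
    if grid is not None:
        spacing, origin = grid
    else:
        zooms = img.header.get_zooms()[:3]
        if any(z <= 0 for z in zooms):
            raise ValidationError(f"{path}: header field pixdim (spacing) missing or non-positive")
        spacing = tuple(float(z) * 1e3 for z in zooms)
        origin = tuple(float(img.affine[a, 3]) * 1e3 for a in range(3))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    return data, spacing, origin


def write_volume(volume: ImageVolume, path) -> Path:
    """Write a scalar volume as NIfTI (float64 voxels, exact grid extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = _nifti_for(volume.values.astype(np.float64), volume.spacing, volume.origin)
    nib.save(img, str(path))
    return path


def read_volume(path) -> ImageVolume:
    """Read a scalar NIfTI volume written by :func:`write_volume` (or any 3D NIfTI)."""
    data, spacing, origin = _load_nifti(path)
    return ImageVolume(np.asarray(data, dtype=np.float64), spacing, origin)


def write_labels(labels: LabelVolume, path, code_table: dict | None = None) -> Path:
    """Write a label volume as uint8 NIfTI plus a ``.codes.json`` table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = _nifti_for(labels.labels.astype(np.uint8), labels.spacing, labels.origin)
    nib.save(img, str(path))
    table = code_table if code_table is not None else TISSUE_CODE_TABLE
    with open(f"{path}.codes.json", "w") as fh:
        json.dump({str(k): v for k, v in table.items()}, fh, indent=1)
    return path


def read_labels(path) -> LabelVolume:
    data, spacing, origin = _load_nifti(path)
    data = np.asarray(data)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.rint(data)):
            raise ValidationError(f"{path}: label volume holds non-integer values")
        data = np.rint(data).astype(np.uint8)
    return LabelVolume(data, spacing, origin)


def write_volume_tiff(volume: ImageVolume, path) -> Path:
    """Export a volume as a multi-page TIFF stack (pages along z)."""
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # pages along the slice axis; in-plane resolution recorded in μm
    stack = np.moveaxis(volume.values.astype(np.float32), 2, 0)
    tifffile.imwrite(
        str(path),
        stack,
        resolution=(1e4 / volume.spacing[0], 1e4 / volume.spacing[1]),
        metadata={"spacing_um": list(volume.spacing), "origin_um": list(volume.origin)},
    )
    return path


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Full parameterization of a simulate→segment→quantify→compare run.

    Every defaulted field is materialized on write, so an emitted config
    file re-runs identically; thresholds and geometric constants used in a
    run always appear in it.
    """

    seed: int = 0
    days: tuple[int, ...] = (10, 14, 21)
    n_per_day: int = 5
    phantom: dict = field(default_factory=dict)
    intensity_model: dict = field(default_factory=dict)
    thresholds: dict = field(
        default_factory=lambda: {
            "bone": [1.0, 3.4],
            "fibrous_or_marrow": [3.4, 5.5],
            "cartilage": [5.5, 6.2],
            "fold_sub_bone": True,
        }
    )
    uct_threshold: float = UCT_BONE_THRESHOLD_MG_HA_CM3
    stats: dict = field(default_factory=lambda: {"paired": True, "alpha": 0.05})
    #: emulate biological inter-animal variability (composition, callus size,
    #: positioning) around the per-day means; without it every specimen of a
    #: day is geometrically identical and correlations are undefined
    vary_specimens: bool = True
    save_volumes: bool = False
    verbosity: int = 1

    def build_thresholds(self) -> TissueThresholds:
        t = TissueThresholds(
            bone=tuple(self.thresholds["bone"]),
            fibrous_or_marrow=tuple(self.thresholds["fibrous_or_marrow"]),
            cartilage=tuple(self.thresholds["cartilage"]),
            fold_sub_bone=bool(self.thresholds.get("fold_sub_bone", True)),
        )
        t.validate()
        return t

    def build_model(self) -> TissueIntensityModel:
        kwargs = {
            k: (tuple(v) if isinstance(v, (list, tuple)) else v)
            for k, v in self.intensity_model.items()
        }
        model = TissueIntensityModel(**kwargs)
        model.validate()
        return model

    def build_spec(self, day: int, seed: int) -> PhantomSpec:
        kwargs = dict(self.phantom)
        for key in ("pin_positions", "mri_spacing", "mri_shape", "uct_spacing"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if "target_fractions" in kwargs and kwargs["target_fractions"] is not None:
            kwargs["target_fractions"] = dict(kwargs["target_fractions"])
        spec = PhantomSpec(healing_day=day, seed=seed, **kwargs)
        spec.validate()
        return spec

    def validate(self) -> None:
        if self.n_per_day < 3:
            raise ValidationError("n_per_day must be >= 3 (correlation requires n >= 3)")
        if self.uct_threshold <= 0:
            raise ValidationError("uct_threshold must be > 0")
        self.build_thresholds()
        self.build_model()
        for day in self.days:
            self.build_spec(day, 0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["days"] = list(self.days)
        # materialize every phantom/model default so the file is self-contained
        spec = self.build_spec(self.days[0], self.seed)
        mat = dataclasses.asdict(spec)
        mat.pop("healing_day")
        mat.pop("seed")
        for k, v in mat.items():
            d["phantom"].setdefault(k, list(v) if isinstance(v, tuple) else v)
        model = self.build_model()
        for k, v in dataclasses.asdict(model).items():
            d["intensity_model"].setdefault(k, list(v) if isinstance(v, tuple) else v)
        return d


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "days" in raw:
        raw["days"] = tuple(raw["days"])
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def save_config(config: RunConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return path


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the fully materialized configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
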