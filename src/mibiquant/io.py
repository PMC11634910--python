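"""NIfTI-based file interchange and provenance records.

Volumes travel as ``.nii``/``.nii.gz`` with the voxel spacing in the
header; the unit tag (counts, Bq/mL, SUV g/mL) lives in a JSON sidecar
``<stem>.json`` next to the image rather than in header free-text fields.
Planar views are stored as 2D NIfTI with the pixel pitch and view label in
the same sidecar.  Every pipeline run writes a machine-readable provenance
record (config + seed + package version) alongside its outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .types import ImageVolume, PlanarImage, VoiMask, VolumeIOError

__all__ = [
    "read_volume",
    "write_volume",
    "read_planar",
    "write_planar",
    "write_mask",
    "read_mask",
    "write_provenance",
    "RunConfig",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI plus a JSON sidecar carrying the unit tag."""
    path = Path(path)
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(volume.values, affine), str(path))
    _sidecar_path(path).write_text(
        json.dumps({"unit": volume.unit, "spacing_mm": list(volume.spacing_mm)}, indent=1)
    )
    return path


def read_volume(path: str | Path, unit: str | None = None) -> ImageVolume:
    """Load a 3D NIfTI volume; the unit comes from the sidecar or ``unit``.

    Missing or non-positive spacing is a hard error; anisotropic spacing is
    accepted (the parameter formulas use the true voxel volume).
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeIOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise VolumeIOError(f"{path} is not a 3D volume (ndim={data.ndim})")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise VolumeIOError(f"{path} has missing or non-positive voxel spacing {spacing}")
    meta = _read_sidecar(path)
    unit = meta.get("unit", unit)
    if unit is None:
        raise VolumeIOError(f"{path}: no unit tag in sidecar and none supplied")
    return ImageVolume(data, spacing, unit)


def write_planar(image: PlanarImage, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag(list(image.pixel_mm) + [1.0, 1.0])
    nib.save(nib.Nifti1Image(image.values[..., None], affine), str(path))
    _sidecar_path(path).write_text(
        json.dumps({"view": image.view, "pixel_mm": list(image.pixel_mm)}, indent=1)
    )
    return path


def read_planar(path: str | Path, view: str | None = None) -> PlanarImage:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
    except Exception as exc:
        raise VolumeIOError(f"cannot read planar image {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 2:
        raise VolumeIOError(f"{path} is not a planar image")
    meta = _read_sidecar(path)
    view = meta.get("view", view)
    if view is None:
        raise VolumeIOError(f"{path}: no view label in sidecar and none supplied")
    pixel = meta.get("pixel_mm") or [float(z) for z in img.header.get_zooms()[:2]]
    return PlanarImage(data, tuple(pixel), view)  # type: ignore[arg-type]


def write_mask(mask: VoiMask, spacing_mm, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag(list(spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine), str(path))
    _sidecar_path(path).write_text(json.dumps({"label": mask.label}, indent=1))
    return path


def read_mask(path: str | Path, label: str = "tumor") -> VoiMask:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    img = nib.load(str(path))
    meta = _read_sidecar(path)
    return VoiMask(np.asarray(img.get_fdata()) > 0.5, meta.get("label", label))  # type: ignore[arg-type]


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (synthetic-cohort mode)."""

    out_dir: str = "mibiquant_run"
    n_subjects: int = 18
    seed: int = 0
    wor_basis: str = "mean"
    attenuation_per_cm: float = 0.0
    noise_scale: float = 0.0
    missing_delayed: int = 1  # subjects without a delayed scan
    make_figures: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def as_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "n_subjects": self.n_subjects,
            "seed": self.seed,
            "wor_basis": self.wor_basis,
            "attenuation_per_cm": self.attenuation_per_cm,
            "noise_scale": self.noise_scale,
            "missing_delayed": self.missing_delayed,
            "make_figures": self.make_figures,
        }


def write_provenance(out_dir: str | Path, config: dict, seed: int) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec = {"config": config, "seed": seed, "package": "mibiquant", "version": __version__}
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(rec, indent=1, sort_keys=True))
    return path
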