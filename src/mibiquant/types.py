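"""Core in-memory containers shared by all pipeline stages.

Physical conventions used throughout the package:

* Volumes are stored as ``(nx, ny, nz)`` arrays of floats.  Axis ``x`` runs
  left-right, ``y`` anterior-posterior (the projection axis of a
  craniocaudal planar view), and ``z`` cranio-caudal.
* Physical coordinates are voxel-center millimetres with the origin at the
  geometric centre of the grid, so a volume is symmetric about ``(0, 0, 0)``.
* A value grid always carries a unit tag: raw detector ``counts``, activity
  concentration ``Bq/mL``, or body-weight-normalised uptake ``SUV g/mL``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "UNIT_COUNTS",
    "UNIT_BQ_ML",
    "UNIT_SUV",
    "ImageVolume",
    "PlanarImage",
    "VoiMask",
    "PlanarRoi",
    "AcquisitionMeta",
    "SpectParamSet",
    "WorResult",
    "MbiParamSet",
    "GeometryError",
    "CalibrationError",
    "SegmentationError",
    "UnitError",
    "VolumeIOError",
    "TC99M_HALF_LIFE_H",
]

UNIT_COUNTS = "counts"
UNIT_BQ_ML = "Bq/mL"
UNIT_SUV = "SUV g/mL"

#: Physical half-life of Tc-99m in hours, used for decay correction of the
#: injected activity between injection and scan start.
TC99M_HALF_LIFE_H = 6.0058


class GeometryError(ValueError):
    """A spatial specification is inconsistent (object outside grid, ...)."""


class CalibrationError(ValueError):
    """Missing or non-positive calibration constants (sensitivity, dose, ...)."""


class SegmentationError(ValueError):
    """Delineation cannot proceed (e.g. flat-zero search region)."""


class UnitError(ValueError):
    """An operation received a grid with the wrong unit tag."""


class VolumeIOError(IOError):
    """A volume or planar image on disk is unreadable or malformed."""


@dataclass
class ImageVolume:
    """A 3D scalar field with voxel spacing and a unit tag."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    unit: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)  # type: ignore[assignment]
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be three positive lengths, got {self.spacing_mm}")
        if not self.unit:
            raise UnitError("unit tag must be set")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mL(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along ``axis``, origin at the grid centre."""
        n = self.values.shape[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.spacing_mm[axis]

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "ImageVolume":
        return ImageVolume(values, self.spacing_mm, unit if unit is not None else self.unit)


@dataclass
class PlanarImage:
    """A 2D scalar grid (counts) with pixel spacing and a view label."""

    values: np.ndarray
    pixel_mm: tuple[float, float]
    view: Literal["CC", "MLO", "LAT"]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"expected a 2D grid, got ndim={self.values.ndim}")
        self.pixel_mm = tuple(float(p) for p in self.pixel_mm)  # type: ignore[assignment]
        if len(self.pixel_mm) != 2 or any(p <= 0 for p in self.pixel_mm):
            raise ValueError(f"pixel_mm must be two positive lengths, got {self.pixel_mm}")
        if self.view not in ("CC", "MLO", "LAT"):
            raise ValueError(f"unknown view label {self.view!r}")


@dataclass
class VoiMask:
    """Boolean voxel mask congruent with an :class:`ImageVolume`."""

    mask: np.ndarray
    label: Literal["tumor", "background"]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("VOI mask must be 3D")
        if self.label not in ("tumor", "background"):
            raise ValueError(f"unknown VOI label {self.label!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def volume_mL(self, volume: ImageVolume) -> float:
        return self.n_voxels * volume.voxel_volume_mL


@dataclass
class PlanarRoi:
    """Boolean pixel mask on a planar view."""

    mask: np.ndarray
    label: Literal["tumor", "background"]
    view: Literal["CC", "MLO", "LAT"]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("planar ROI mask must be 2D")
        if not self.mask.any():
            raise ValueError("planar ROI is empty")


@dataclass
class AcquisitionMeta:
    """Injection, timing and calibration metadata for one acquisition.

    Parameters
    ----------
    injected_activity_MBq
        Administered activity at injection time (the study protocol uses
        600 MBq of Tc-99m-sestamibi).
    injection_time_h, scan_start_time_h
        Timestamps in hours on a common clock; only the difference matters.
    body_weight_kg
        Patient mass used for body-weight SUV normalisation.
    camera_sensitivity_cps_per_MBq
        System volume sensitivity used to convert reconstructed counts into
        activity concentration.
    acq_duration_s
        Acquisition duration in seconds.
    """

    injected_activity_MBq: float
    injection_time_h: float
    scan_start_time_h: float
    body_weight_kg: float
    camera_sensitivity_cps_per_MBq: float = 90.0
    acq_duration_s: float = 1500.0

    def __post_init__(self) -> None:
        if self.injected_activity_MBq <= 0:
            raise CalibrationError("injected activity must be positive")
        if self.body_weight_kg <= 0:
            raise CalibrationError("body weight must be positive")
        if self.scan_start_time_h < self.injection_time_h:
            raise ValueError("scan cannot start before injection")

    @property
    def uptake_time_h(self) -> float:
        return self.scan_start_time_h - self.injection_time_h

    def decay_corrected_activity_Bq(self) -> float:
        """Injected activity decayed from injection to scan start, in Bq."""
        decay = 0.5 ** (self.uptake_time_h / TC99M_HALF_LIFE_H)
        return self.injected_activity_MBq * 1.0e6 * decay


@dataclass
class SpectParamSet:
    """Semi-quantitative SPECT parameters of one lesion at one time point.

    ``tlmu`` (total lesion mitochondrial uptake) is defined as
    ``ftv_mL * suv_mean`` and carries gram units; ``cov_pct`` is the
    intra-lesion coefficient of variation ``100 * suv_sd / suv_mean``.
    """

    suv_max: float
    suv_mean: float
    suv_sd: float
    ftv_mL: float
    tlmu: float
    tbr_max: float
    tbr_mean: float
    cov_pct: float
    n_voxels: int = 0

    def as_dict(self, prefix: str = "") -> dict[str, float]:
        return {
            f"{prefix}suv_max": self.suv_max,
            f"{prefix}suv_mean": self.suv_mean,
            f"{prefix}suv_sd": self.suv_sd,
            f"{prefix}ftv_mL": self.ftv_mL,
            f"{prefix}tlmu": self.tlmu,
            f"{prefix}tbr_max": self.tbr_max,
            f"{prefix}tbr_mean": self.tbr_mean,
            f"{prefix}cov_pct": self.cov_pct,
        }


@dataclass
class WorResult:
    """Wash-out rate between the early and delayed acquisitions (percent).

    Positive values mean tracer loss between the two time points, negative
    values continued accumulation.  ``tbr_basis`` records whether the
    tumor-to-background ratio fed to the formula was the mean- or
    max-based variant.
    """

    wor_pct: float
    tbr_basis: Literal["mean", "max"]


@dataclass
class MbiParamSet:
    """Planar-MBI semi-quantitative parameters of one lesion.

    ``cov_norm`` is a background-normalised heterogeneity index that keeps
    counts units (it scales with acquisition duration), unlike the two
    percentage variants.
    """

    ftv_mL: float
    mean_counts: float
    tbr_max: float
    tbr_ave: float
    cov_max_pct: float
    cov_ave_pct: float
    cov_norm: float
    diameters_mm: tuple[float, float, float] = field(default=(np.nan,) * 3)

    def as_dict(self, prefix: str = "mbi_") -> dict[str, float]:
        return {
            f"{prefix}ftv_mL": self.ftv_mL,
            f"{prefix}mean_counts": self.mean_counts,
            f"{prefix}tbr_max": self.tbr_max,
            f"{prefix}tbr_ave": self.tbr_ave,
            f"{prefix}cov_max_pct": self.cov_max_pct,
            f"{prefix}cov_ave_pct": self.cov_ave_pct,
            f"{prefix}cov_norm": self.cov_norm,
        }
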