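"""SPECT semi-quantitative analysis.

The chain mirrors the clinical workflow on reconstructed prone SPECT/CT
volumes: counts are converted to activity concentration with the camera
calibration, normalised to body-weight SUV (g/mL), the tumor is delineated
with a 42% threshold iso-contour around the hottest voxel, background is
sampled with a ~3 cm sphere in the contralateral breast, and the
semi-quantitative parameter set is computed:

* SUV_max, SUV_mean and their SD over the tumor VOI,
* FTV — functional tumor volume (VOI voxel volume, mL),
* TLMU — total lesion mitochondrial uptake, FTV x SUV_mean (g),
* TBR_max = SUV_max,tumor / SUV_mean,background and
  TBR_mean = SUV_mean,tumor / SUV_mean,background,
* COV = 100 x SD / SUV_mean (percent), an intra-tumor heterogeneity proxy,
* WOR = 100 x (TBR_early - TBR_late) / TBR_early, the dual-time-point
  wash-out rate (positive = tracer loss, negative = continued uptake).
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np
from scipy import ndimage

from .types import (
    UNIT_BQ_ML,
    UNIT_COUNTS,
    UNIT_SUV,
    AcquisitionMeta,
    CalibrationError,
    GeometryError,
    ImageVolume,
    SegmentationError,
    SpectParamSet,
    UnitError,
    VoiMask,
    WorResult,
)

__all__ = [
    "counts_to_activity",
    "activity_to_counts",
    "activity_to_suv",
    "segment_tumor_iso42",
    "background_voi_sphere",
    "compute_spect_params",
    "compute_wor",
]

log = logging.getLogger(__name__)

#: Fractional iso-contour threshold used for tumor delineation.
ISO_THRESHOLD = 0.42

# 26-neighbourhood: any voxel sharing a face, edge or corner.
_CONN26 = np.ones((3, 3, 3), dtype=bool)


def counts_to_activity(volume: ImageVolume, meta: AcquisitionMeta) -> ImageVolume:
    """Convert a reconstructed counts volume to activity concentration.

    ``Bq/mL = counts / (sensitivity_cps_per_MBq * duration_s * voxel_mL) * 1e6``

    The camera volume-sensitivity calibration replaces the vendor's
    proprietary conversion; its contract (counts in, Bq/mL out) is the same.
    """
    if volume.unit != UNIT_COUNTS:
        raise UnitError(f"expected a counts volume, got unit {volume.unit!r}")
    if meta.camera_sensitivity_cps_per_MBq <= 0 or meta.acq_duration_s <= 0:
        raise CalibrationError("camera sensitivity and acquisition duration must be positive")
    denom = meta.camera_sensitivity_cps_per_MBq * meta.acq_duration_s * volume.voxel_volume_mL
    return volume.with_values(volume.values / denom * 1.0e6, UNIT_BQ_ML)


def activity_to_counts(volume: ImageVolume, meta: AcquisitionMeta) -> ImageVolume:
    """Exact inverse of :func:`counts_to_activity` (useful for simulation)."""
    if volume.unit != UNIT_BQ_ML:
        raise UnitError(f"expected a Bq/mL volume, got unit {volume.unit!r}")
    if meta.camera_sensitivity_cps_per_MBq <= 0 or meta.acq_duration_s <= 0:
        raise CalibrationError("camera sensitivity and acquisition duration must be positive")
    denom = meta.camera_sensitivity_cps_per_MBq * meta.acq_duration_s * volume.voxel_volume_mL
    return volume.with_values(volume.values * denom / 1.0e6, UNIT_COUNTS)


def activity_to_suv(volume: ImageVolume, meta: AcquisitionMeta) -> ImageVolume:
    """Normalise activity concentration to body-weight SUV (g/mL).

    ``SUV = C / (A_decayed / m)`` with ``C`` in Bq/mL, the injected
    activity decay-corrected from injection to scan start (Tc-99m half-life
    6.0058 h) and the body mass in grams.  A tissue density of 1 g/mL is
    assumed so that SUV carries g/mL units.
    """
    if volume.unit != UNIT_BQ_ML:
        raise UnitError(f"expected a Bq/mL volume, got unit {volume.unit!r}")
    dose_bq = meta.decay_corrected_activity_Bq()
    weight_g = meta.body_weight_kg * 1000.0
    return volume.with_values(volume.values / (dose_bq / weight_g), UNIT_SUV)


def _as_region(volume: ImageVolume, search_region) -> np.ndarray:
    """Normalise a search-region argument (VoiMask, bool array or index box)."""
    if search_region is None:
        return np.ones(volume.shape, dtype=bool)
    if isinstance(search_region, VoiMask):
        region = search_region.mask
    elif isinstance(search_region, np.ndarray):
        region = search_region.astype(bool)
    else:  # ((x0, x1), (y0, y1), (z0, z1)) half-open index box
        region = np.zeros(volume.shape, dtype=bool)
        (x0, x1), (y0, y1), (z0, z1) = search_region
        region[x0:x1, y0:y1, z0:z1] = True
    if region.shape != volume.shape:
        raise GeometryError("search region shape does not match the volume")
    return region


def segment_tumor_iso42(
    volume: ImageVolume, search_region=None, threshold: float = ISO_THRESHOLD
) -> VoiMask:
    """Delineate the tumor with a fractional iso-contour.

    Keeps the voxels of the search region whose value is at least
    ``threshold`` (default 42%) of the region maximum, restricted to the
    26-connected component containing the hottest voxel — a deterministic
    stand-in for the semi-automatic seed-and-adjust delineation done on a
    workstation.  The result always contains the maximum voxel.
    """
    region = _as_region(volume, search_region)
    if not region.any():
        raise SegmentationError("search region is empty")
    vals = volume.values
    vmax = vals[region].max()
    if vmax <= 0:
        raise SegmentationError("search region has no positive voxels")
    above = region & (vals >= threshold * vmax)
    labels, _ = ndimage.label(above, structure=_CONN26)
    flat = np.flatnonzero(region & (vals == vmax))
    seed = np.unravel_index(flat[0], vals.shape)
    mask = labels == labels[seed]
    return VoiMask(mask, "tumor")


def background_voi_sphere(
    volume: ImageVolume, center_mm: tuple[float, float, float], diameter_mm: float = 30.0
) -> VoiMask:
    """Spherical background VOI (default ~3 cm, contralateral breast).

    Selects the voxels whose centres lie within ``diameter_mm / 2`` of the
    given physical centre (origin at the grid centre).  The sphere must be
    fully inside the grid: a truncated background sample would bias the
    TBR denominator, so clipping raises a :class:`GeometryError`.  If the
    radius is below the voxel size the single nearest voxel is returned.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter_mm must be positive")
    r = diameter_mm / 2.0
    coords = [volume.axis_coords_mm(a) for a in range(3)]
    for a in range(3):
        lo, hi = coords[a][0], coords[a][-1]
        if center_mm[a] - r < lo - volume.spacing_mm[a] / 2 or center_mm[a] + r > hi + volume.spacing_mm[a] / 2:
            raise GeometryError("background sphere is clipped by the grid boundary")
    d2 = (
        (coords[0][:, None, None] - center_mm[0]) ** 2
        + (coords[1][None, :, None] - center_mm[1]) ** 2
        + (coords[2][None, None, :] - center_mm[2]) ** 2
    )
    mask = d2 <= r * r
    if not mask.any():
        idx = np.unravel_index(np.argmin(d2), d2.shape)
        mask[idx] = True
    return VoiMask(mask, "background")


def compute_spect_params(
    volume: ImageVolume, tumor: VoiMask, background: VoiMask
) -> SpectParamSet:
    """Compute the full SPECT parameter set for one lesion/time point.

    SD is the population standard deviation over the tumor voxels; FTV is
    the tumor voxel count times the voxel volume.
    """
    if volume.unit != UNIT_SUV:
        raise UnitError(f"expected an SUV volume, got unit {volume.unit!r}")
    if not tumor.mask.any() or not background.mask.any():
        raise ValueError("tumor and background masks must be non-empty")
    if (tumor.mask & background.mask).any():
        raise ValueError("tumor and background masks overlap")
    tv = volume.values[tumor.mask]
    bg_mean = float(volume.values[background.mask].mean())
    if bg_mean <= 0:
        raise ZeroDivisionError("background SUV mean is zero; TBR undefined")
    suv_max = float(tv.max())
    suv_mean = float(tv.mean())
    suv_sd = float(tv.std(ddof=0))
    if tv.size == 1:
        log.warning("single-voxel tumor VOI: SD and COV are 0 by definition")
    ftv = tumor.volume_mL(volume)
    return SpectParamSet(
        suv_max=suv_max,
        suv_mean=suv_mean,
        suv_sd=suv_sd,
        ftv_mL=ftv,
        tlmu=ftv * suv_mean,
        tbr_max=suv_max / bg_mean,
        tbr_mean=suv_mean / bg_mean,
        cov_pct=100.0 * suv_sd / suv_mean if suv_mean > 0 else 0.0,
        n_voxels=int(tv.size),
    )


def compute_wor(
    early: SpectParamSet, late: SpectParamSet, basis: Literal["mean", "max"] = "mean"
) -> WorResult:
    """Dual-time-point wash-out rate, percent.

    ``WOR = 100 * (TBR_early - TBR_late) / TBR_early`` on the chosen TBR
    basis (mean by default; the basis used is recorded in the result).
    """
    if basis not in ("mean", "max"):
        raise ValueError(f"unknown TBR basis {basis!r}")
    attr = f"tbr_{basis}"
    tbr_e = getattr(early, attr)
    tbr_l = getattr(late, attr)
    if tbr_e <= 0:
        raise ZeroDivisionError("early TBR must be positive to define WOR")
    return WorResult(wor_pct=100.0 * (tbr_e - tbr_l) / tbr_e, tbr_basis=basis)
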