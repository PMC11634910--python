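"""Digital breast phantom: paired early/delayed activity volumes and
forward-projected planar views.

The phantom emulates the dual-time-point study design: a prone-breast
acquisition at 5 min post injection and a delayed one at 90 min.  A breast
is modelled as an axis-aligned ellipsoid of uniform background activity
containing a single ellipsoidal tumor whose activity is
``background * tbr_true`` modulated by a smooth multiplicative texture
field.  The delayed volume is the early volume with the tumor scaled by
``1 - washout_fraction`` (background static), so the analytic wash-out rate
of the phantom is exactly ``100 * washout_fraction``.

Planar views mimic a dedicated breast gamma camera: parallel-ray line
integrals along the view axis at 3.20 mm pixels, optionally with
exponential depth attenuation (the planar modality has no attenuation
correction — the phantom can reproduce that bias) and Poisson counting
noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import (
    UNIT_BQ_ML,
    GeometryError,
    ImageVolume,
    PlanarImage,
    VoiMask,
)

__all__ = [
    "TumorPhantomSpec",
    "PhantomTruth",
    "generate_phantom_pair",
    "project_mbi",
    "planar_point_px",
]

log = logging.getLogger(__name__)

#: Linear attenuation coefficient of soft tissue at 140 keV, 1/cm.
SOFT_TISSUE_MU_140KEV = 0.15

_VIEWS = ("CC", "MLO", "LAT")
# Projection axis per view; MLO additionally rotates 45 deg about z first.
_PROJ_AXIS = {"CC": 1, "MLO": 1, "LAT": 0}
_MLO_ANGLE_DEG = 45.0


@dataclass
class TumorPhantomSpec:
    """Geometry, contrast and noise specification of one phantom subject.

    Parameters
    ----------
    breast_shape_mm
        Full extents of the breast ellipsoid along (x, y, z).
    tumor_center_mm
        Tumor centre in physical coordinates (origin = breast centre).
        The default is deliberately not commensurate with the voxel
        lattice: grid-aligned placement is a degenerate special case whose
        voxelization errors are atypically correlated across the tumor
        surface.
    tumor_diameters_mm
        Three perpendicular tumor diameters (a, b, c) along (x, y, z).
    tbr_true
        Target tumor-to-background activity ratio.
    cov_true
        Target voxel-level coefficient of variation inside the tumor, in
        percent.  0 gives a uniform tumor.
    washout_fraction
        Fractional loss of tumor activity between the early and delayed
        volumes; negative values model continued accumulation.
    background_activity
        Breast background activity concentration, Bq/mL.
    voxel_mm
        Isotropic voxel edge length; the default matches a 2.21 mm
        reconstructed SPECT grid.
    noise_scale
        Expected counts per Bq/mL for voxelwise Poisson sampling; 0
        disables noise.
    seed
        RNG seed; identical (spec, seed) yields bit-identical volumes.
    """

    breast_shape_mm: tuple[float, float, float] = (160.0, 100.0, 100.0)
    tumor_center_mm: tuple[float, float, float] = (30.0, 1.5, 1.0)
    tumor_diameters_mm: tuple[float, float, float] = (30.0, 25.0, 20.0)
    tbr_true: float = 6.0
    cov_true: float = 10.0
    washout_fraction: float = 0.18
    background_activity: float = 1000.0
    voxel_mm: float = 2.21
    noise_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.breast_shape_mm = tuple(float(v) for v in self.breast_shape_mm)  # type: ignore[assignment]
        self.tumor_center_mm = tuple(float(v) for v in self.tumor_center_mm)  # type: ignore[assignment]
        self.tumor_diameters_mm = tuple(float(v) for v in self.tumor_diameters_mm)  # type: ignore[assignment]
        if any(d <= 0 for d in self.tumor_diameters_mm):
            raise GeometryError("tumor diameters must all be positive")
        if any(b <= 0 for b in self.breast_shape_mm):
            raise GeometryError("breast extents must all be positive")
        if self.tbr_true <= 0:
            raise ValueError("tbr_true must be positive")
        if self.cov_true < 0:
            raise ValueError("cov_true must be non-negative")
        if not -1.0 <= self.washout_fraction <= 1.0:
            raise ValueError("washout_fraction must lie in [-1, 1]")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        if self.background_activity < 0:
            raise ValueError("background_activity must be non-negative")
        self._check_containment()

    def _check_containment(self) -> None:
        """Reject tumors protruding outside the breast ellipsoid.

        Samples the tumor surface densely (Fibonacci sphere) and evaluates
        the breast quadratic form at each point; sufficient in practice for
        axis-aligned ellipsoids.
        """
        n = 512
        k = np.arange(n)
        phi = np.arccos(1 - 2 * (k + 0.5) / n)
        theta = np.pi * (1 + 5**0.5) * k
        u = np.stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
        )
        semi_t = np.asarray(self.tumor_diameters_mm) / 2.0
        semi_b = np.asarray(self.breast_shape_mm) / 2.0
        surface = np.asarray(self.tumor_center_mm) + u * semi_t
        q = np.sum((surface / semi_b) ** 2, axis=1)
        if np.any(q > 1.0):
            raise GeometryError(
                "tumor ellipsoid protrudes outside the breast ellipsoid "
                f"(max quadratic form {q.max():.3f} > 1)"
            )

    @property
    def ftv_true_mL(self) -> float:
        a, b, c = self.tumor_diameters_mm
        return np.pi / 6.0 * a * b * c / 1000.0


@dataclass
class PhantomTruth:
    """Ground-truth record accompanying a generated phantom pair."""

    ftv_true_mL: float
    tbr_true: float
    cov_true: float
    wor_true_pct: float
    suv_scalars: dict[str, float]
    tumor_mask: VoiMask | None = None
    background_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tumor_center_mm: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def as_dict(self) -> dict:
        return {
            "ftv_true_mL": self.ftv_true_mL,
            "tbr_true": self.tbr_true,
            "cov_true": self.cov_true,
            "wor_true_pct": self.wor_true_pct,
            "suv_scalars": self.suv_scalars,
            "background_center_mm": list(self.background_center_mm),
            "tumor_center_mm": list(self.tumor_center_mm),
        }


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: float,
    center_mm: tuple[float, float, float],
    diameters_mm: tuple[float, float, float],
) -> np.ndarray:
    """Voxel-centre-inside-ellipsoid indicator on a centred grid."""
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * spacing - c for n, c in zip(shape, center_mm)
    ]
    semi = [d / 2.0 for d in diameters_mm]
    q = (
        (coords[0][:, None, None] / semi[0]) ** 2
        + (coords[1][None, :, None] / semi[1]) ** 2
        + (coords[2][None, None, :] / semi[2]) ** 2
    )
    return q <= 1.0


def _heterogeneity_field(
    shape: tuple[int, int, int], tumor: np.ndarray, cov_frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative texture with exact realised CV over the tumor.

    White Gaussian noise is smoothed with a fixed 1-voxel-sigma kernel and
    affinely rescaled so that mean 1 and SD ``cov_frac`` hold exactly over
    the tumor voxels.  Negative values (possible at high CV) are clamped to
    zero and logged, which perturbs the realised CV only marginally.
    """
    field = np.ones(shape)
    if cov_frac <= 0 or tumor.sum() < 2:
        return field
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=1.0)
    gt = g[tumor]
    sd = gt.std()
    if sd == 0:
        return field
    field = 1.0 + (g - gt.mean()) / sd * cov_frac
    n_neg = int((field[tumor] < 0).sum())
    if n_neg:
        log.warning("clamped %d negative texture voxels to zero", n_neg)
    return np.clip(field, 0.0, None)


def generate_phantom_pair(
    spec: TumorPhantomSpec,
) -> tuple[ImageVolume, ImageVolume, PhantomTruth]:
    """Generate the early (5 min) and delayed (90 min) activity volumes.

    Returns
    -------
    early, delayed : ImageVolume
        Activity concentration volumes in Bq/mL on an isotropic grid two
        voxels larger than the breast on each side.
    truth : PhantomTruth
        Analytic ground truth (ellipsoid tumor volume, contrast,
        heterogeneity, wash-out) plus the noiseless tumor indicator mask
        and the mirrored background-sphere centre.
    """
    pad = 2
    shape = tuple(int(np.ceil(b / spec.voxel_mm)) + 2 * pad for b in spec.breast_shape_mm)
    breast = _ellipsoid_mask(shape, spec.voxel_mm, (0.0, 0.0, 0.0), spec.breast_shape_mm)
    tumor = _ellipsoid_mask(shape, spec.voxel_mm, spec.tumor_center_mm, spec.tumor_diameters_mm)
    tumor &= breast

    rng = np.random.default_rng(spec.seed)
    texture = _heterogeneity_field(shape, tumor, spec.cov_true / 100.0, rng)

    early = np.zeros(shape)
    early[breast] = spec.background_activity
    early[tumor] = spec.background_activity * spec.tbr_true * texture[tumor]

    delayed = early.copy()
    delayed[tumor] = early[tumor] * (1.0 - spec.washout_fraction)

    if spec.noise_scale > 0:
        for arr in (early, delayed):
            counts = rng.poisson(arr * spec.noise_scale)
            arr[:] = counts / spec.noise_scale
        n_neg = int((early < 0).sum() + (delayed < 0).sum())
        if n_neg:  # Poisson draws are non-negative; guard kept for safety
            log.warning("clamped %d negative voxels to zero after noise", n_neg)
        np.clip(early, 0.0, None, out=early)
        np.clip(delayed, 0.0, None, out=delayed)

    spacing = (spec.voxel_mm,) * 3
    vol_early = ImageVolume(early, spacing, UNIT_BQ_ML)
    vol_delayed = ImageVolume(delayed, spacing, UNIT_BQ_ML)

    cx, cy, cz = spec.tumor_center_mm
    truth = PhantomTruth(
        ftv_true_mL=spec.ftv_true_mL,
        tbr_true=spec.tbr_true,
        cov_true=spec.cov_true,
        wor_true_pct=spec.washout_fraction * 100.0,
        suv_scalars={
            "background_activity_Bq_per_mL": spec.background_activity,
            "tumor_activity_Bq_per_mL": spec.background_activity * spec.tbr_true,
        },
        tumor_mask=VoiMask(tumor, "tumor"),
        background_center_mm=(-cx, cy, cz),
        tumor_center_mm=spec.tumor_center_mm,
    )
    return vol_early, vol_delayed, truth


def _depth_weights(n: int, step_cm: float, mu_per_cm: float) -> np.ndarray:
    """Beer–Lambert transmission per plane, detector at plane index 0."""
    return np.exp(-mu_per_cm * np.arange(n) * step_cm)


def _resample_conserving(proj: np.ndarray, spacing: tuple[float, float], pixel_mm: float) -> np.ndarray:
    """Resample a summed projection to the detector pixel grid.

    Values are treated as counts per source-grid pixel; linear
    interpolation of the count *density* followed by multiplication with
    the new pixel area keeps totals approximately conserved.
    """
    density = proj / (spacing[0] * spacing[1])
    zoom = (spacing[0] / pixel_mm, spacing[1] / pixel_mm)
    out = ndimage.zoom(density, zoom, order=1, mode="constant", cval=0.0, prefilter=False)
    return out * pixel_mm * pixel_mm


def project_mbi(
    volume: ImageVolume,
    view: str,
    pixel_mm: float = 3.20,
    attenuation_per_cm: float = 0.0,
    noise_scale: float = 0.0,
    seed: int = 0,
) -> PlanarImage:
    """Forward-project a volume into a planar view.

    Parallel-ray line integrals (plain voxel sums, so total counts are
    conserved) along the view axis: CC sums along y, LAT along x, and MLO
    rotates the volume 45 degrees about the z axis before summing along y.
    Optional exponential depth attenuation weights each plane by
    ``exp(-mu * depth)`` with the detector at the low-index face.  The
    summed projection is then resampled to the requested detector pixel
    pitch; optional Poisson noise models the counting statistics.
    """
    if view not in _VIEWS:
        raise ValueError(f"unknown view label {view!r}; expected one of {_VIEWS}")
    if pixel_mm <= 0:
        raise ValueError("pixel_mm must be positive")
    vals = volume.values
    if not vals.any():
        log.warning("projecting an empty volume; returning a zero image")
    if view == "MLO":
        vals = ndimage.rotate(
            vals, _MLO_ANGLE_DEG, axes=(0, 1), reshape=True, order=1, mode="constant", cval=0.0
        )
        np.clip(vals, 0.0, None, out=vals)
    axis = _PROJ_AXIS[view]
    step_cm = volume.spacing_mm[axis] / 10.0
    if attenuation_per_cm > 0:
        w = _depth_weights(vals.shape[axis], step_cm, attenuation_per_cm)
        w = w.reshape([-1 if a == axis else 1 for a in range(3)])
        vals = vals * w
    proj = vals.sum(axis=axis)
    in_plane = tuple(volume.spacing_mm[a] for a in range(3) if a != axis)
    img = _resample_conserving(proj, in_plane, pixel_mm)
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        img = rng.poisson(np.clip(img, 0.0, None) * noise_scale) / noise_scale
    return PlanarImage(img, (pixel_mm, pixel_mm), view)  # type: ignore[arg-type]


def planar_point_px(
    volume: ImageVolume,
    view: str,
    point_mm: tuple[float, float, float],
    pixel_mm: float = 3.20,
) -> tuple[float, float]:
    """Map a physical point to (fractional) pixel indices of a projected view.

    Mirrors the geometry of :func:`project_mbi`: the volume (and hence the
    point) is rotated about the grid-centre z axis for the MLO view, the
    projection axis is dropped, and the in-plane offset from the grid
    centre is converted to detector pixels.  Accurate to within half a
    pixel of the resampling used in :func:`project_mbi`, which is ample for
    placing centimetre-scale background ROIs.
    """
    if view not in _VIEWS:
        raise ValueError(f"unknown view label {view!r}")
    x, y, z = point_mm
    if view == "MLO":
        th = np.deg2rad(_MLO_ANGLE_DEG)
        # scipy.ndimage.rotate(angle) maps input axes by the inverse rotation;
        # a point fixed in the object appears rotated by -angle in array axes.
        x, y = x * np.cos(th) - y * np.sin(th), x * np.sin(th) + y * np.cos(th)
    axis = _PROJ_AXIS[view]
    in_plane_mm = [v for a, v in enumerate((x, y, z)) if a != axis]
    # Projected image extent per in-plane axis, needed to locate its centre.
    shape = list(volume.shape)
    spacing = list(volume.spacing_mm)
    if view == "MLO":
        # rotate(reshape=True) enlarges the in-plane bounding box
        nx, ny = shape[0], shape[1]
        c, s = abs(np.cos(th)), abs(np.sin(th))
        shape[0] = int(round(nx * c + ny * s))
        shape[1] = int(round(nx * s + ny * c))
    plane_axes = [a for a in range(3) if a != axis]
    out = []
    for a, coord in zip(plane_axes, in_plane_mm):
        # zoom() output size follows round(n * factor)
        n_px = int(round(shape[a] * (spacing[a] / pixel_mm)))
        out.append(coord / pixel_mm + (n_px - 1) / 2.0)
    return tuple(out)  # type: ignore[return-value]
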