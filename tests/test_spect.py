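"""SPECT quantification chain: calibration, SUV, delineation, parameters."""

import numpy as np
import pytest

from mibiquant import (
    AcquisitionMeta,
    GeometryError,
    ImageVolume,
    SegmentationError,
    TumorPhantomSpec,
    UnitError,
    VoiMask,
    activity_to_suv,
    background_voi_sphere,
    compute_spect_params,
    compute_wor,
    counts_to_activity,
    generate_phantom_pair,
    segment_tumor_iso42,
)
from mibiquant.spect import activity_to_counts
from mibiquant.types import UNIT_BQ_ML, UNIT_COUNTS, UNIT_SUV

from conftest import iso42_reference


def _vol(values, spacing=(10.0, 10.0, 10.0), unit=UNIT_SUV):
    return ImageVolume(np.asarray(values, dtype=float), spacing, unit)


class TestCountsToActivity:
    def test_unit_arithmetic(self):
        # 1000 counts / (10 cps/MBq * 100 s * 1 mL) = 1 MBq/mL = 1e6 Bq/mL
        meta = AcquisitionMeta(600, 0, 0, 70, camera_sensitivity_cps_per_MBq=10, acq_duration_s=100)
        vol = _vol(np.full((2, 2, 2), 1000.0), unit=UNIT_COUNTS)  # 1 mL voxels
        out = counts_to_activity(vol, meta)
        assert out.unit == UNIT_BQ_ML
        assert out.values == pytest.approx(1.0e6)

    def test_zero_volume_maps_to_zero(self):
        meta = AcquisitionMeta(600, 0, 0, 70)
        out = counts_to_activity(_vol(np.zeros((3, 3, 3)), unit=UNIT_COUNTS), meta)
        assert (out.values == 0).all()

    def test_roundtrip_with_inverse(self):
        rng = np.random.default_rng(0)
        meta = AcquisitionMeta(600, 0, 0, 70, camera_sensitivity_cps_per_MBq=37.3, acq_duration_s=1234)
        vol = _vol(rng.uniform(0, 5e4, (6, 6, 6)), spacing=(2.21,) * 3, unit=UNIT_BQ_ML)
        back = counts_to_activity(activity_to_counts(vol, meta), meta)
        np.testing.assert_allclose(back.values, vol.values, rtol=1e-12)

    def test_wrong_unit_rejected(self):
        meta = AcquisitionMeta(600, 0, 0, 70)
        with pytest.raises(UnitError):
            counts_to_activity(_vol(np.ones((2, 2, 2)), unit=UNIT_BQ_ML), meta)


class TestActivityToSuv:
    def test_definitional_identity(self):
        """Concentration equal to dose-per-gram gives SUV exactly 1."""
        meta = AcquisitionMeta(600, 0.0, 0.0, 60.0)
        c = meta.decay_corrected_activity_Bq() / (60.0 * 1000.0)
        out = activity_to_suv(_vol(np.full((3, 3, 3), c), unit=UNIT_BQ_ML), meta)
        assert out.unit == UNIT_SUV
        assert out.values == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # zero elapsed time, 600 MBq, 60 kg, C = 10 kBq/mL -> SUV 1.0
        meta = AcquisitionMeta(600, 0.0, 0.0, 60.0)
        out = activity_to_suv(_vol(np.full((2, 2, 2), 1.0e4), unit=UNIT_BQ_ML), meta)
        assert out.values == pytest.approx(1.0)

    def test_body_weight_linearity(self):
        vol = _vol(np.full((2, 2, 2), 1.0e4), unit=UNIT_BQ_ML)
        light = activity_to_suv(vol, AcquisitionMeta(600, 0, 0, 60.0))
        heavy = activity_to_suv(vol, AcquisitionMeta(600, 0, 0, 120.0))
        np.testing.assert_allclose(heavy.values, 2.0 * light.values)

    def test_decay_correction_uses_tc99m_half_life(self):
        """After one half-life of uptake time the SUV doubles."""
        vol = _vol(np.full((2, 2, 2), 1.0e4), unit=UNIT_BQ_ML)
        now = activity_to_suv(vol, AcquisitionMeta(600, 0.0, 0.0, 60.0))
        later = activity_to_suv(vol, AcquisitionMeta(600, 0.0, 6.0058, 60.0))
        np.testing.assert_allclose(later.values, 2.0 * now.values, rtol=1e-12)


class TestSegmentation:
    def test_threshold_arithmetic(self):
        """Values {10, 5, 4, 1}: threshold 4.2 keeps only {10, 5}."""
        vals = np.zeros((4, 1, 1))
        vals[:, 0, 0] = [10.0, 5.0, 4.0, 1.0]
        mask = segment_tumor_iso42(_vol(vals))
        assert vals[mask.mask].tolist() == [10.0, 5.0]

    def test_disjoint_hot_spot_excluded(self):
        vals = np.zeros((9, 1, 1))
        vals[0:2, 0, 0] = [10.0, 6.0]
        vals[6:8, 0, 0] = [7.0, 7.0]  # above threshold but not connected to max
        mask = segment_tumor_iso42(_vol(vals))
        assert set(np.flatnonzero(mask.mask)) == {0, 1}

    def test_flat_zero_region_rejected(self):
        with pytest.raises(SegmentationError):
            segment_tumor_iso42(_vol(np.zeros((3, 3, 3))))

    def test_mask_always_contains_max_voxel(self):
        rng = np.random.default_rng(4)
        vals = rng.exponential(1.0, (12, 12, 12))
        mask = segment_tumor_iso42(_vol(vals))
        assert mask.mask[np.unravel_index(np.argmax(vals), vals.shape)]

    def test_matches_bruteforce_reference_on_random_volumes(self):
        """Exhaustive scan-and-flood-fill oracle equivalence (voxel-exact)."""
        rng = np.random.default_rng(1234)
        for _ in range(20):
            shape = tuple(rng.integers(4, 17, size=3))
            vals = rng.uniform(0, 1, shape) ** 3
            region = np.ones(shape, dtype=bool)
            got = segment_tumor_iso42(ImageVolume(vals, (1, 1, 1), UNIT_SUV), region)
            ref = iso42_reference(vals, region)
            np.testing.assert_array_equal(got.mask, ref)

    def test_search_region_limits_threshold_reference(self):
        """42% is taken of the region max, not the global max."""
        vals = np.zeros((10, 1, 1))
        vals[0, 0, 0] = 100.0  # hot voxel outside the search box
        vals[5:8, 0, 0] = [10.0, 5.0, 1.0]
        mask = segment_tumor_iso42(_vol(vals), ((4, 9), (0, 1), (0, 1)))
        assert set(np.flatnonzero(mask.mask)) == {5, 6}


class TestBackgroundVoi:
    def test_sphere_volume_against_bruteforce_center_count(self):
        vol = _vol(np.ones((41, 41, 41)), spacing=(2.21,) * 3)
        mask = background_voi_sphere(vol, (1.0, 0.5, -0.8), 30.0)
        coords = [vol.axis_coords_mm(a) for a in range(3)]
        inside = 0
        for i, x in enumerate(coords[0]):
            for j, y in enumerate(coords[1]):
                for k, z in enumerate(coords[2]):
                    if (x - 1.0) ** 2 + (y - 0.5) ** 2 + (z + 0.8) ** 2 <= 15.0**2:
                        inside += 1
        assert mask.n_voxels == inside
        # voxelized volume tracks the analytic 14.14 mL within a surface band
        band = 4 * np.pi * 15.0**2 * 2.21 / 1000.0
        assert abs(mask.volume_mL(vol) - np.pi / 6 * 3.0**3) < band / 2

    def test_degenerate_small_sphere_single_voxel(self):
        vol = _vol(np.ones((11, 11, 11)), spacing=(2.21,) * 3)
        mask = background_voi_sphere(vol, (0.3, 0.1, 0.0), 1.0)
        assert mask.n_voxels == 1

    def test_clipped_sphere_rejected(self):
        vol = _vol(np.ones((11, 11, 11)), spacing=(2.21,) * 3)
        with pytest.raises(GeometryError):
            background_voi_sphere(vol, (11 * 2.21 / 2, 0, 0), 30.0)


class TestSpectParams:
    def _masks(self, n_tumor, n_bg, shape):
        tumor = np.zeros(shape, dtype=bool)
        bg = np.zeros(shape, dtype=bool)
        tumor.flat[:n_tumor] = True
        bg.flat[-n_bg:] = True
        return VoiMask(tumor, "tumor"), VoiMask(bg, "background")

    def test_uniform_tumor_hand_values(self):
        vals = np.full((8, 1, 1), 1.0)
        vals[:5, 0, 0] = 4.0
        vol = _vol(vals)  # 1 mL voxels
        tumor, bg = self._masks(5, 3, vals.shape)
        p = compute_spect_params(vol, tumor, bg)
        assert (p.suv_max, p.suv_mean, p.suv_sd) == (4.0, 4.0, 0.0)
        assert p.ftv_mL == pytest.approx(5.0)
        assert p.tlmu == pytest.approx(20.0)
        assert p.tbr_max == p.tbr_mean == pytest.approx(4.0)
        assert p.cov_pct == 0.0

    def test_three_voxel_hand_values(self):
        vals = np.full((6, 1, 1), 2.0)
        vals[:3, 0, 0] = [2.0, 4.0, 6.0]
        vol = _vol(vals)
        tumor, bg = self._masks(3, 3, vals.shape)
        p = compute_spect_params(vol, tumor, bg)
        assert p.suv_mean == pytest.approx(4.0)
        assert p.suv_sd == pytest.approx(np.sqrt(8.0 / 3.0), abs=1e-12)  # 1.633
        assert p.ftv_mL == pytest.approx(3.0)
        assert p.tlmu == pytest.approx(12.0)
        assert p.tbr_max == pytest.approx(3.0)
        assert p.tbr_mean == pytest.approx(2.0)
        assert p.cov_pct == pytest.approx(40.82, abs=0.01)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0.5, 5.0, (6, 6, 6))
        vol = _vol(vals, spacing=(2.0, 2.0, 2.0))
        tumor, bg = self._masks(30, 40, vals.shape)
        k = 3.7
        p1 = compute_spect_params(vol, tumor, bg)
        p2 = compute_spect_params(vol.with_values(k * vals), tumor, bg)
        assert p2.suv_max == pytest.approx(k * p1.suv_max)
        assert p2.suv_mean == pytest.approx(k * p1.suv_mean)
        assert p2.suv_sd == pytest.approx(k * p1.suv_sd)
        assert p2.ftv_mL == p1.ftv_mL
        assert p2.tbr_max == pytest.approx(p1.tbr_max)
        assert p2.tbr_mean == pytest.approx(p1.tbr_mean)
        assert p2.cov_pct == pytest.approx(p1.cov_pct)

    def test_tlmu_identity_machine_precision(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(0.1, 9.0, (7, 7, 7))
        vol = _vol(vals, spacing=(2.21,) * 3)
        tumor, bg = self._masks(50, 60, vals.shape)
        p = compute_spect_params(vol, tumor, bg)
        assert p.tlmu == p.ftv_mL * p.suv_mean

    def test_overlapping_masks_rejected(self):
        vals = np.ones((4, 4, 4))
        tumor, _ = self._masks(10, 5, vals.shape)
        with pytest.raises(ValueError, match="overlap"):
            compute_spect_params(_vol(vals), tumor, tumor)


class TestWor:
    def _params(self, tbr_mean, tbr_max=None):
        from mibiquant import SpectParamSet

        return SpectParamSet(
            suv_max=1, suv_mean=1, suv_sd=0, ftv_mL=1, tlmu=1,
            tbr_max=tbr_max if tbr_max is not None else tbr_mean,
            tbr_mean=tbr_mean, cov_pct=0,
        )

    def test_halving_gives_fifty_percent(self):
        wor = compute_wor(self._params(10.0), self._params(5.0))
        assert wor.wor_pct == pytest.approx(50.0)
        assert wor.tbr_basis == "mean"

    def test_equal_tbr_gives_zero(self):
        assert compute_wor(self._params(4.2), self._params(4.2)).wor_pct == 0.0

    def test_uptake_increase_gives_negative_wor(self):
        assert compute_wor(self._params(3.0), self._params(4.0)).wor_pct < 0

    def test_max_basis_recorded_and_used(self):
        wor = compute_wor(self._params(5, tbr_max=8), self._params(5, tbr_max=4), basis="max")
        assert wor.wor_pct == pytest.approx(50.0)
        assert wor.tbr_basis == "max"

    def test_nonpositive_early_tbr_rejected(self):
        with pytest.raises(ZeroDivisionError):
            compute_wor(self._params(0.0), self._params(1.0))


class TestPhantomRecovery:
    def test_tbr_cov_and_wor_recovery(self, meta_early):
        """Parameter recovery on a noiseless heterogeneous phantom."""
        spec = TumorPhantomSpec(
            tbr_true=6.0, cov_true=10.0, washout_fraction=0.30, noise_scale=0.0, seed=17
        )
        early, delayed, truth = generate_phantom_pair(spec)
        suv_e = activity_to_suv(early, meta_early)
        suv_d = activity_to_suv(delayed, meta_early)
        tumor_e = segment_tumor_iso42(suv_e, truth.tumor_mask.mask)
        tumor_d = segment_tumor_iso42(suv_d, truth.tumor_mask.mask)
        bg_e = background_voi_sphere(suv_e, truth.background_center_mm)
        p_e = compute_spect_params(suv_e, tumor_e, bg_e)
        p_d = compute_spect_params(suv_d, tumor_d, bg_e)
        assert p_e.tbr_mean == pytest.approx(6.0, rel=0.10)
        assert p_e.cov_pct == pytest.approx(10.0, abs=3.0)
        wor = compute_wor(p_e, p_d)
        assert wor.wor_pct == pytest.approx(truth.wor_true_pct, abs=3.0)

    def test_wor_strictly_increases_with_washout_fraction(self, meta_early):
        wors = []
        for w in (-0.33, 0.0, 0.18, 0.45):
            spec = TumorPhantomSpec(washout_fraction=w, noise_scale=0.0, seed=19)
            early, delayed, truth = generate_phantom_pair(spec)
            suv_e = activity_to_suv(early, meta_early)
            suv_d = activity_to_suv(delayed, meta_early)
            bg = background_voi_sphere(suv_e, truth.background_center_mm)
            p_e = compute_spect_params(suv_e, segment_tumor_iso42(suv_e, truth.tumor_mask.mask), bg)
            p_d = compute_spect_params(suv_d, segment_tumor_iso42(suv_d, truth.tumor_mask.mask), bg)
            wors.append(compute_wor(p_e, p_d).wor_pct)
        assert all(a < b for a, b in zip(wors, wors[1:]))
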