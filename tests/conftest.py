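import numpy as np
import pytest

from mibiquant import AcquisitionMeta, TumorPhantomSpec


@pytest.fixture
def meta_early():
    """600 MBq injection, early scan 5 min p.i., 70 kg subject."""
    return AcquisitionMeta(
        injected_activity_MBq=600.0,
        injection_time_h=0.0,
        scan_start_time_h=5.0 / 60.0,
        body_weight_kg=70.0,
    )


@pytest.fixture
def default_spec():
    return TumorPhantomSpec(seed=11)


@pytest.fixture
def uniform_sphere_spec():
    """Noiseless homogeneous 30 mm spherical tumor at contrast 6."""
    return TumorPhantomSpec(
        tumor_diameters_mm=(30.0, 30.0, 30.0), cov_true=0.0, washout_fraction=0.18, seed=7
    )


def iso42_reference(values: np.ndarray, region: np.ndarray, threshold: float = 0.42):
    """Brute-force threshold-and-flood-fill segmentation reference.

    Scans the region for the maximum, thresholds, and grows the
    26-connected component from the maximum voxel with an explicit
    breadth-first frontier expansion; independent of the production path.
    """
    vmax = values[region].max()
    above = region & (values >= threshold * vmax)
    seed_flat = np.flatnonzero(region & (values == vmax))[0]
    seed = np.unravel_index(seed_flat, values.shape)
    grown = np.zeros_like(above)
    grown[seed] = True
    while True:
        frontier = np.zeros_like(grown)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if dx == dy == dz == 0:
                        continue
                    shifted = np.roll(grown, (dx, dy, dz), axis=(0, 1, 2))
                    # roll wraps around; kill the wrapped faces
                    if dx == 1:
                        shifted[0, :, :] = False
                    elif dx == -1:
                        shifted[-1, :, :] = False
                    if dy == 1:
                        shifted[:, 0, :] = False
                    elif dy == -1:
                        shifted[:, -1, :] = False
                    if dz == 1:
                        shifted[:, :, 0] = False
                    elif dz == -1:
                        shifted[:, :, -1] = False
                    frontier |= shifted
        new = grown | (frontier & above)
        if (new == grown).all():
            return new
        grown = new
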