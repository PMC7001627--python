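"""Shared fixtures: small, fast synthetic scenes used across the suite."""

import numpy as np
import pytest

import isospim as iso


@pytest.fixture(scope="session")
def system_geometry() -> iso.ScanGeometry:
    """The bead-characterization scan geometry: 280 nm steps tilted
    10°/10°, 1.625×1.625×4.5 µm LR voxels, 4×4×2 enhancement."""
    return iso.ScanGeometry(
        step_nm=280.0,
        tilt_first_deg=10.0,
        tilt_second_deg=10.0,
        n_frames=1,
        lr_voxel_um=(1.625, 1.625, 4.5),
        enhancement=(4, 4, 2),
    )


@pytest.fixture(scope="session")
def system_psf() -> iso.PSFModel:
    return iso.PSFModel(lateral_fwhm_um=4.2, axial_fwhm_um=12.0)


@pytest.fixture(scope="session")
def quiet_camera() -> iso.CameraModel:
    return iso.CameraModel(pixel_um=1.625, read_noise_sd=0.0, poisson=False,
                           seed=7)


@pytest.fixture(scope="session")
def single_bead_phantom() -> iso.Phantom:
    return iso.Phantom(
        beads=[iso.Bead((20.0, 18.0, 22.0), peak=1000.0, diameter_um=0.5)],
        bounds_um=((4.0, 36.0), (4.0, 32.0), (4.0, 40.0)),
    )


@pytest.fixture(scope="session")
def single_bead_sequence(single_bead_phantom, system_psf,
                         system_geometry, quiet_camera):
    """Noise-free tilted scan of one bead (shared: simulation is the
    costly part of many SVR tests)."""
    return iso.simulate_scan(
        single_bead_phantom, system_psf, system_geometry, quiet_camera
    )


@pytest.fixture(scope="session")
def single_bead_groups(single_bead_sequence):
    plan = iso.grouping_plan(single_bead_sequence.geometry, 4.5)
    return iso.extract_lr_groups(single_bead_sequence, plan), plan


@pytest.fixture(scope="session")
def single_bead_svr(single_bead_groups, system_psf, single_bead_sequence):
    """Converged-enough single-view SVR of the shared bead scene."""
    groups, _ = single_bead_groups
    vol, log = iso.run_svr(
        groups, system_psf, single_bead_sequence.geometry,
        iso.SVRConfig(max_iterations=30, rel_tolerance=1e-6),
    )
    return vol, log


def centroid_um_xyz(volume: iso.HRVolume) -> np.ndarray:
    """Intensity-weighted centroid in (x, y, z) µm (test helper)."""
    a = np.asarray(volume.data, dtype=np.float64)
    idx = np.indices(a.shape)
    s = a.sum()
    czyx = np.array([(i * a).sum() / s for i in idx])
    return (czyx * volume.voxel_zyx + volume.origin_zyx)[::-1]
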