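"""SVR reconstruction: decimation bookkeeping, offset estimation, the
forward operator and its adjoint, the ML iteration, and realignment."""

import dataclasses

import numpy as np
import pytest

import isospim as iso
from isospim.geometry import grouping_plan
from isospim.svr import SVRConfig, TooFewFramesError, _SVRProblem
from isospim.volume import HRVolume

from conftest import centroid_um_xyz


class TestExtractLRGroups:
    def test_single_phase_is_whole_stack(self, quiet_camera):
        geom = iso.ScanGeometry(1000.0, 0.0, 0.0, n_frames=8,
                                lr_voxel_um=(1.0, 1.0, 1.0))
        frames = np.random.default_rng(0).random((8, 4, 4)).astype(np.float32)
        raw = iso.RawSequence(frames=frames, geometry=geom)
        plan = grouping_plan(geom, 1.0)
        groups = iso.extract_lr_groups(raw, plan)
        assert len(groups) == 1
        assert np.allclose(groups[0].stack, frames)
        assert groups[0].offset_hr_voxels == (0.0, 0.0, 0.0)

    def test_34_frames_17_phases_disjoint_cover(self, system_geometry):
        geom = dataclasses.replace(system_geometry, n_frames=34)
        frames = np.arange(34, dtype=np.float32)[:, None, None] * np.ones(
            (34, 3, 3), dtype=np.float32
        )
        raw = iso.RawSequence(frames=frames, geometry=geom)
        plan = grouping_plan(geom, 4.5)
        groups = iso.extract_lr_groups(raw, plan)
        assert len(groups) == 17
        assert all(g.stack.shape[0] == 2 for g in groups)
        prov = sorted(i for g in groups for i in g.provenance)
        assert prov == list(range(34))

    def test_too_few_frames(self, system_geometry):
        geom = dataclasses.replace(system_geometry, n_frames=10)
        raw = iso.RawSequence(frames=np.zeros((10, 3, 3)), geometry=geom)
        with pytest.raises(TooFewFramesError):
            iso.extract_lr_groups(raw, grouping_plan(geom, 4.5))

    def test_group_centroids_shift_axially_by_scan_steps(
        self, single_bead_groups
    ):
        """In the stacked scan frame the group offsets are purely axial:
        group j's bead centroid sits j scan steps earlier along z, and
        the lateral centroids coincide (the oblique sample-frame offset
        j·d is bookkeeping, not a stack-coordinate displacement)."""
        groups, plan = single_bead_groups
        dz = plan.step_um_xyz[2]

        def centroid_lr(g):
            a = g.stack
            idx = np.indices(a.shape)
            return np.array([(i * a).sum() / a.sum() for i in idx])

        c0 = centroid_lr(groups[0])
        for j in (3, 9, 16):
            diff = centroid_lr(groups[j]) - c0
            assert diff[0] * plan.lr_axial_spacing_um == pytest.approx(
                -j * dz, abs=0.1 * plan.lr_axial_spacing_um
            )
            assert abs(diff[1]) < 1e-4
            assert abs(diff[2]) < 1e-4
            # sample-frame bookkeeping: offsets are exactly j*d/hr_voxel
            assert np.allclose(
                groups[j].offset_hr_voxels,
                j * np.asarray(plan.step_um_xyz) / np.asarray(plan.hr_voxel_um),
            )


class TestEstimateOffsets:
    def test_identical_stacks_zero_offset(self, single_bead_groups):
        groups, _ = single_bead_groups
        twin = [groups[0], groups[0]]
        off = iso.estimate_offsets(twin, (4, 4, 2))
        assert np.abs(off[1]).max() < 1e-3

    def test_recovers_known_scan_offsets(self, single_bead_groups):
        groups, _ = single_bead_groups
        est = iso.estimate_offsets(groups, (4, 4, 2))
        for j in (1, 5, 11, 16):
            nominal = groups[j].scan_offset_hr_voxels
            assert np.abs(est[j] - nominal).max() < 0.1

    def test_pure_noise_falls_back_to_nominal(self, single_bead_groups):
        groups, _ = single_bead_groups
        rng = np.random.default_rng(9)
        noisy = []
        for g in groups[:3]:
            noisy.append(
                dataclasses.replace(
                    g, stack=rng.random(g.stack.shape)
                )
            )
        with pytest.warns(UserWarning, match="falling back"):
            off = iso.estimate_offsets(noisy, (4, 4, 2), min_confidence=0.9)
        assert np.allclose(off[1], noisy[1].scan_offset_hr_voxels)


class TestInitialGuess:
    def test_identity_enhancement_copies_with_floor(self, single_bead_groups):
        groups, _ = single_bead_groups
        g = groups[0]
        ig = iso.initial_guess(g, (1, 1, 1))
        mask = g.stack > g.stack.mean()
        assert np.allclose(ig.data[mask], g.stack[mask])
        assert ig.data.min() > 0

    def test_shape_arithmetic(self, single_bead_groups):
        groups, _ = single_bead_groups
        z, y, x = groups[0].stack.shape
        ig = iso.initial_guess(groups[0], (4, 4, 2))
        assert ig.data.shape == (2 * z, 4 * y, 4 * x)

    def test_flux_preserved(self, single_bead_groups):
        groups, _ = single_bead_groups
        g = groups[0]
        lr_flux = g.stack.sum() * np.prod(g.lr_voxel_um)
        ig = iso.initial_guess(g, (4, 4, 2))
        hr_flux = ig.data.sum() * np.prod(ig.voxel_um)
        assert hr_flux == pytest.approx(lr_flux, rel=0.01)


class TestForwardProject:
    def test_linear_zero_maps_to_zero(self):
        hr = HRVolume(np.zeros((4, 8, 8)), (0.5, 0.5, 1.0))
        out = iso.forward_project(hr, (0.0, 0.0, 0.0), None, (2, 2, 2))
        assert out.shape == (2, 4, 4)
        assert np.all(out == 0)

    def test_delta_psf_identity_chain(self):
        rng = np.random.default_rng(1)
        data = rng.random((4, 8, 8))
        hr = HRVolume(data, (0.5, 0.5, 1.0))
        out = iso.forward_project(hr, (0.0, 0.0, 0.0), None, (1, 1, 1))
        assert np.allclose(out, data)


class TestRunSVR:
    def test_single_group_delta_psf_exact_fixed_point(self):
        rng = np.random.default_rng(2)
        stack = rng.random((4, 6, 6)) + 0.5
        g = iso.LRGroup(
            stack=stack,
            offset_hr_voxels=(0.0, 0.0, 0.0),
            scan_offset_hr_voxels=np.zeros(3),
            provenance=(0, 1, 2, 3),
            lr_voxel_um=(1.0, 1.0, 1.0),
        )
        geom = iso.ScanGeometry(1000.0, 0.0, 0.0, enhancement=(1, 1, 1))
        vol, log = iso.run_svr([g], None, geom,
                               SVRConfig(max_iterations=1))
        assert np.allclose(vol.data, stack, rtol=1e-10)

    def test_all_zero_data_warns_and_returns_zero(self):
        g = iso.LRGroup(
            stack=np.zeros((2, 4, 4)),
            offset_hr_voxels=(0.0, 0.0, 0.0),
            scan_offset_hr_voxels=np.zeros(3),
            provenance=(0, 1),
            lr_voxel_um=(1.0, 1.0, 1.0),
        )
        geom = iso.ScanGeometry(1000.0, 0.0, 0.0, enhancement=(1, 1, 1))
        with pytest.warns(UserWarning, match="all-zero"):
            vol, _ = iso.run_svr([g], None, geom)
        assert np.all(vol.data == 0)

    def test_kl_monotone_nonincreasing(self, single_bead_svr):
        """The multiplicative Poisson update never increases the
        data-fit KL divergence on noise-free inputs."""
        _, log = single_bead_svr
        kl = log["kl"].to_numpy()
        assert np.all(np.diff(kl) <= 1e-9 * abs(kl[0]) + 1e-12)

    def test_non_negativity_and_flux(self, single_bead_svr, single_bead_groups):
        vol, _ = single_bead_svr
        groups, _ = single_bead_groups
        assert vol.data.min() >= 0
        data_flux = groups[0].stack.sum() * np.prod(groups[0].lr_voxel_um)
        est_flux = vol.data.sum() * np.prod(vol.voxel_um)
        assert est_flux == pytest.approx(data_flux, rel=0.02)

    def test_resolution_enhanced_below_raw(self, single_bead_svr,
                                           single_bead_sequence,
                                           single_bead_phantom):
        """Converged FWHM is strictly below the raw optics in every axis
        (4.2 µm lateral, 12 µm axial) given ≥2× axial oversampling."""
        vol, _ = single_bead_svr
        cart = iso.realign(vol, single_bead_sequence.geometry)
        c = single_bead_phantom.beads[0].center_um
        fx = iso.measure_fwhm(cart, c, "x", expected_fwhm_um=2.0)
        fy = iso.measure_fwhm(cart, c, "y", expected_fwhm_um=2.0)
        fz = iso.measure_fwhm(cart, c, "z", expected_fwhm_um=5.0)
        assert fx < 4.2 and fy < 4.2
        assert fz < 12.0

    def test_matches_dense_matrix_ml_oracle(self):
        """run_svr agrees per-iteration (1e-6) with an explicit dense-
        matrix implementation of the same multiplicative update on a
        tiny 8×8×4 instance."""
        rng = np.random.default_rng(4)
        geom = iso.ScanGeometry(
            500.0, 8.0, 0.0, lr_voxel_um=(1.0, 1.0, 1.0),
            enhancement=(2, 2, 2),
        )
        psf = iso.PSFModel(1.5, 2.0)
        groups = []
        n_groups = 3
        for j in range(n_groups):
            groups.append(
                iso.LRGroup(
                    stack=rng.random((2, 4, 4)) + 0.2,
                    offset_hr_voxels=(0.0, 0.0, 0.0),
                    scan_offset_hr_voxels=np.array([j * 2 / 3.0, 0.0, 0.0]),
                    provenance=(j,),
                    lr_voxel_um=(1.0, 1.0, 1.0),
                )
            )
        # dense forward matrices probed from the same linear operator
        prob = _SVRProblem(groups, psf, geom, (2, 2, 2))
        hr_shape, lr_shape = prob.hr_shape, prob.lr_shape
        n = int(np.prod(hr_shape))
        m = int(np.prod(lr_shape))
        A = np.zeros((n_groups, m, n))
        for i in range(n):
            e = np.zeros(n)
            e[i] = 1.0
            b = prob.blur(e.reshape(hr_shape))
            for j in range(n_groups):
                A[j][:, i] = prob.project_group(b, j).ravel()
        ys = [g.stack.ravel() for g in groups]
        x = iso.initial_guess(groups[0], (2, 2, 2), 1e-6).data.ravel()
        eps = 1e-6 * x.mean()
        denom = sum(Aj.T @ np.ones(m) for Aj in A)
        n_iter = 3
        for _ in range(n_iter):
            num = sum(
                Aj.T @ (y / np.maximum(Aj @ x, eps)) for Aj, y in zip(A, ys)
            )
            x = x * num / np.maximum(denom, eps)
        vol, _ = iso.run_svr(
            groups, psf, geom,
            SVRConfig(max_iterations=n_iter, rel_tolerance=1e-12),
        )
        ref = x.reshape(hr_shape)
        assert np.abs(vol.data - ref).max() <= 1e-6 * ref.max()


class TestRealign:
    def test_untilted_identity(self, single_bead_groups):
        groups, _ = single_bead_groups
        geom = iso.ScanGeometry(1000.0, 0.0, 0.0)
        vol = HRVolume(groups[0].stack.copy(), groups[0].lr_voxel_um,
                       frame="scan")
        out = iso.realign(vol, geom, mode="nearest")
        assert np.array_equal(out.data, vol.data)
        assert out.frame == "cartesian"

    def test_bead_position_recovered(self, single_bead_svr,
                                     single_bead_sequence,
                                     single_bead_phantom):
        """Realignment restores the true Cartesian bead position; the
        scan-frame position differs by the shear."""
        vol, _ = single_bead_svr
        truth = np.array(single_bead_phantom.beads[0].center_um)
        scan_pos = centroid_um_xyz(vol)
        cart = iso.realign(vol, single_bead_sequence.geometry)
        cart_pos = centroid_um_xyz(cart)
        hr_vox = max(cart.voxel_um)
        assert np.abs(cart_pos - truth).max() < hr_vox
        assert np.abs(scan_pos - truth).max() > 2 * hr_vox

    def test_realign_shear_roundtrip_psnr(self, system_geometry):
        """realign ∘ shear returns a smooth volume within interpolation
        tolerance (PSNR > 40 dB on the shared interior)."""
        from scipy import ndimage

        rng = np.random.default_rng(5)
        cart = ndimage.gaussian_filter(rng.random((24, 48, 48)), 3.0)
        cart_vol = HRVolume(cart, (0.5, 0.5, 1.0))
        sheared = iso.resample(
            cart_vol,
            iso.shear_matrix(system_geometry).inverse(),
            cart_vol,
        )
        sheared.frame = "scan"
        sheared.meta["shear_anchor_z_um"] = 0.0
        back = iso.realign(sheared, system_geometry)
        # compare on the interior region shared by both grids
        idx = np.round(
            (cart_vol.origin_zyx - back.origin_zyx) / back.voxel_zyx
        ).astype(int)
        sub = back.data[
            idx[0]: idx[0] + 24, idx[1]: idx[1] + 48, idx[2]: idx[2] + 48
        ]
        core = (slice(4, 20), slice(8, 40), slice(8, 40))
        err = sub[core] - cart[core]
        psnr = 10 * np.log10(cart.max() ** 2 / np.mean(err**2))
        assert psnr > 40.0
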