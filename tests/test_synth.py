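"""Phantom generation and image-formation simulation."""

import dataclasses

import numpy as np
import pytest

import isospim as iso
from isospim.synth import OversamplingError, PhantomCapacityError


class TestPSFModel:
    def test_rendered_psf_normalized_and_fwhm_consistent(self):
        """A rendered PSF sums to 1 and its measured FWHM matches the
        model within 2% at ≥4 samples per FWHM."""
        psf = iso.PSFModel(4.2, 12.0)
        k = psf.render((0.5, 0.5, 1.5))
        assert k.min() >= 0
        assert k.sum() == pytest.approx(1.0, abs=1e-9)
        center = tuple(s // 2 for s in k.shape)
        # measure FWHM from second moments of axis profiles
        for ax, voxel, expected in ((0, 1.5, 12.0), (1, 0.5, 4.2), (2, 0.5, 4.2)):
            sl = list(center)
            sl[ax] = slice(None)
            prof = k[tuple(sl)]
            xs = (np.arange(prof.size) - center[ax]) * voxel
            var = (xs**2 * prof).sum() / prof.sum()
            assert 2.3548 * np.sqrt(var) == pytest.approx(expected, rel=0.02)

    def test_invalid_fwhm_rejected(self):
        with pytest.raises(ValueError):
            iso.PSFModel(-1.0, 12.0)


class TestBeadPhantom:
    def test_empty_phantom(self):
        ph = iso.make_bead_phantom(0, ((0, 10), (0, 10), (0, 10)), seed=1)
        assert ph.is_empty()

    def test_min_separation_respected(self):
        ph = iso.make_bead_phantom(
            10, ((0, 100), (0, 100), (0, 100)),
            min_separation_um=10.0, seed=1,
        )
        assert len(ph.beads) == 10
        pts = np.array([b.center_um for b in ph.beads])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 10.0

    def test_deterministic_given_seed(self):
        kw = dict(bounds_um=((0, 50), (0, 50), (0, 50)),
                  min_separation_um=5.0, seed=42)
        a = iso.make_bead_phantom(8, **kw)
        b = iso.make_bead_phantom(8, **kw)
        assert a.to_json_dict() == b.to_json_dict()

    def test_cylinder_region_keeps_beads_inside_rotations(self):
        ph = iso.make_bead_phantom(
            30, ((0, 40), (0, 40), (0, 40)), seed=3, region="cylinder"
        )
        c = np.array(ph.center_um)
        for b in ph.beads:
            p = np.array(b.center_um)
            r = np.hypot(p[0] - c[0], p[2] - c[2])
            assert r <= 20.0 + 1e-9

    def test_capacity_error(self):
        with pytest.raises(PhantomCapacityError):
            iso.make_bead_phantom(
                50, ((0, 10), (0, 10), (0, 10)),
                min_separation_um=8.0, seed=1, max_tries=200,
            )


class TestFilamentPhantom:
    def test_deterministic_and_bounded(self):
        kw = dict(bounds_um=((0, 30), (0, 30), (0, 30)), radius_um=0.5, seed=7)
        a = iso.make_filament_phantom(3, **kw)
        b = iso.make_filament_phantom(3, **kw)
        assert a.to_json_dict() == b.to_json_dict()
        for f in a.filaments:
            pts = np.array(f.points_um)
            assert pts.min() >= 0.0 and pts.max() <= 30.0

    def test_empty(self):
        assert iso.make_filament_phantom(
            0, ((0, 10), (0, 10), (0, 10))
        ).is_empty()


class TestRenderVolume:
    def test_empty_phantom_renders_zero(self):
        ph = iso.Phantom(bounds_um=((0, 10), (0, 10), (0, 10)))
        vol = iso.render_volume(ph, (0.5, 0.5, 0.5))
        assert vol.data.sum() == 0.0

    def test_flux_conservation_unblurred(self):
        bead = iso.Bead((10.0, 10.0, 10.0), peak=3.0, diameter_um=1.0)
        ph = iso.Phantom(beads=[bead], bounds_um=((0, 20), (0, 20), (0, 20)))
        vol = iso.render_volume(ph, (0.5, 0.5, 0.5), pad_um=4.0)
        assert vol.physical_flux() == pytest.approx(bead.flux, rel=0.01)

    def test_flux_conservation_blurred(self):
        bead = iso.Bead((15.0, 15.0, 20.0), peak=1.0, diameter_um=0.5)
        ph = iso.Phantom(beads=[bead], bounds_um=((0, 30), (0, 30), (0, 40)))
        vol = iso.render_volume(
            ph, (0.5, 0.5, 1.0), psf=iso.PSFModel(4.2, 12.0), pad_um=20.0
        )
        assert vol.physical_flux() == pytest.approx(bead.flux, rel=0.01)

    def test_blurred_bead_fwhm_matches_psf(self):
        """A 0.5 µm bead imaged with a 4.2/12 µm PSF measures 4.2 µm
        lateral and 12 µm axial within fit tolerance."""
        bead = iso.Bead((32.0, 32.0, 48.0), peak=10.0, diameter_um=0.5)
        ph = iso.Phantom(beads=[bead], bounds_um=((0, 64), (0, 64), (0, 96)))
        vol = iso.render_volume(
            ph, (1.0, 1.0, 1.5), psf=iso.PSFModel(4.2, 12.0), pad_um=10.0
        )
        lat = iso.measure_fwhm(vol, bead.center_um, "x", expected_fwhm_um=4.2)
        axial = iso.measure_fwhm(vol, bead.center_um, "z", expected_fwhm_um=12.0)
        # bead diameter adds ≈ 0.3% in quadrature
        assert lat == pytest.approx(np.hypot(4.2, 0.5), rel=0.02)
        assert axial == pytest.approx(np.hypot(12.0, 0.5), rel=0.02)

    def test_filament_cross_section_fwhm(self):
        """A straight tube's rendered cross-section is the tube profile
        convolved with the lateral PSF (Gaussian quadrature sum)."""
        fil = iso.Filament(
            points_um=((15.0, 2.0, 15.0), (15.0, 28.0, 15.0)),
            radius_um=1.0, intensity=5.0,
        )
        ph = iso.Phantom(filaments=[fil],
                         bounds_um=((0, 30), (0, 30), (0, 30)))
        psf = iso.PSFModel(3.0, 6.0)
        vol = iso.render_volume(ph, (0.4, 0.4, 0.8), psf=psf, pad_um=8.0)
        f = iso.measure_fwhm(vol, (15.0, 15.0, 15.0), "x", expected_fwhm_um=4.0)
        expected = np.hypot(2.0 * fil.radius_um, psf.lateral_fwhm_um)
        assert f == pytest.approx(expected, rel=0.03)


class TestSimulateScan:
    def test_zero_phantom_zero_frames(self, system_psf, system_geometry,
                                      quiet_camera):
        ph = iso.Phantom(bounds_um=((0, 10), (0, 10), (0, 10)))
        seq = iso.simulate_scan(ph, system_psf, system_geometry,
                                quiet_camera)
        assert np.all(seq.frames == 0)

    def test_deterministic_with_noise(self, single_bead_phantom, system_psf,
                                      system_geometry):
        cam = iso.CameraModel(pixel_um=1.625, read_noise_sd=2.0, poisson=True,
                              seed=5)
        a = iso.simulate_scan(single_bead_phantom, system_psf,
                              system_geometry, cam)
        b = iso.simulate_scan(single_bead_phantom, system_psf,
                              system_geometry, cam)
        assert np.array_equal(a.frames, b.frames)

    def test_brightest_frame_matches_bead_axial_position(
        self, single_bead_sequence, single_bead_phantom
    ):
        seq = single_bead_sequence
        d = iso.step_displacement(seq.geometry)
        totals = seq.frames.sum(axis=(1, 2))
        i_max = int(np.argmax(totals))
        z_of_peak = seq.origin_um[2] + i_max * d.dz / 1000.0
        assert abs(z_of_peak - single_bead_phantom.beads[0].center_um[2]) <= (
            d.dz / 1000.0
        )

    def test_oversampling_precondition(self, single_bead_phantom, quiet_camera):
        geom = iso.ScanGeometry(step_nm=15000.0, tilt_first_deg=10.0,
                                tilt_second_deg=10.0)
        with pytest.raises(OversamplingError):
            iso.simulate_scan(single_bead_phantom, iso.PSFModel(4.2, 12.0),
                              geom, quiet_camera)

    def test_bead_and_volume_paths_agree(self, quiet_camera):
        """The analytic bead frame path matches the generic rendered-
        volume interpolation path."""
        bead = iso.Bead((12.0, 12.0, 12.0), peak=100.0, diameter_um=0.5)
        ph = iso.Phantom(beads=[bead], bounds_um=((2, 22), (2, 22), (2, 22)))
        psf = iso.PSFModel(3.0, 6.0)
        geom = iso.ScanGeometry(1000.0, 10.0, 10.0, lr_voxel_um=(1.0, 1.0, 3.0))
        cam = dataclasses.replace(quiet_camera, pixel_um=1.0)
        analytic = iso.simulate_scan(ph, psf, geom, cam)
        # force the generic path by adding a zero-intensity filament
        ph2 = iso.Phantom(
            beads=[bead],
            filaments=[iso.Filament(((3.0, 3.0, 3.0), (4.0, 4.0, 4.0)),
                                    0.5, 0.0)],
            bounds_um=ph.bounds_um,
        )
        generic = iso.simulate_scan(ph2, psf, geom, cam)
        assert analytic.frames.shape == generic.frames.shape
        scale = analytic.frames.max()
        assert np.abs(analytic.frames - generic.frames).max() < 0.05 * scale


class TestAttenuation:
    def test_transmittance_monotone_and_floored(self):
        att = iso.AttenuationModel(length_scale_um=20.0, floor=0.05)
        depths = np.linspace(0, 200, 50)
        t = att.transmittance(depths)
        assert np.all(np.diff(t) <= 0)
        assert t.min() == pytest.approx(0.05)

    def test_deep_bead_dimmed_per_closed_form(self, quiet_camera):
        """Identical beads at increasing illumination depth dim by
        exp(-depth/ℓ); frame intensities follow the closed form."""
        beads = [
            iso.Bead((10.0, 15.0, 15.0), peak=100.0),
            iso.Bead((30.0, 15.0, 15.0), peak=100.0),
        ]
        ph = iso.Phantom(beads=beads, bounds_um=((0, 40), (0, 30), (0, 30)))
        psf = iso.PSFModel(3.0, 6.0)
        geom = iso.ScanGeometry(1000.0, 0.0, 0.0, lr_voxel_um=(1.0, 1.0, 3.0))
        att = iso.AttenuationModel(length_scale_um=10.0)
        cam = dataclasses.replace(quiet_camera, pixel_um=1.0)
        seq = iso.simulate_scan(ph, psf, geom, cam, attenuation=att)
        seq0 = iso.simulate_scan(ph, psf, geom, cam, attenuation=None)
        # both beads share the axial plane: compare lateral halves
        i = int(np.argmax(seq.frames.sum(axis=(1, 2))))
        x_px = ((np.array([10.0, 30.0]) - seq.origin_um[0]) / 1.0).astype(int)
        ratio = []
        for xc in x_px:
            on = seq.frames[i, :, xc - 3: xc + 4].sum()
            off = seq0.frames[i, :, xc - 3: xc + 4].sum()
            ratio.append(on / off)
        # depth is measured from the sample (bounds) entry face at x = 0
        depth = np.array([10.0, 30.0])
        expected = np.exp(-depth / 10.0)
        assert np.allclose(ratio, expected, rtol=0.05)


class TestMultiview:
    def test_single_view_equals_scan(self, single_bead_phantom, system_psf,
                                     system_geometry, quiet_camera):
        seqs = iso.simulate_multiview(
            single_bead_phantom, system_psf, system_geometry,
            quiet_camera, n_views=1,
        )
        direct = iso.simulate_scan(
            single_bead_phantom, system_psf, system_geometry,
            quiet_camera,
        )
        assert np.array_equal(seqs[0].frames, direct.frames)

    def test_rotated_bead_positions_match_pose(self, quiet_camera):
        """Per-view bead image positions match the view-pose prediction
        within one LR voxel (recovered from the frames themselves)."""
        bead = iso.Bead((20.0, 15.0, 10.0), peak=100.0, diameter_um=0.5)
        ph = iso.Phantom(beads=[bead], bounds_um=((0, 30), (0, 30), (0, 30)))
        psf = iso.PSFModel(3.0, 6.0)
        geom = iso.ScanGeometry(1000.0, 0.0, 0.0, lr_voxel_um=(1.0, 1.0, 3.0))
        cam = dataclasses.replace(quiet_camera, pixel_um=1.0)
        seqs = iso.simulate_multiview(ph, psf, geom, cam, n_views=8)
        from isospim.transforms import xyz_to_zyx

        center = xyz_to_zyx(ph.center_um)
        truth = xyz_to_zyx(bead.center_um)
        d = iso.step_displacement(geom)
        for v, seq in enumerate(seqs):
            pose = iso.view_pose(v, 8, center_um=center)
            expect = pose.rigid.apply(truth)  # (z, y, x)
            fr = seq.frames
            i, py, px = np.unravel_index(np.argmax(fr), fr.shape)
            got = np.array([
                seq.origin_um[2] + i * d.dz / 1000.0,
                seq.origin_um[1] + py * cam.pixel_um,
                seq.origin_um[0] + px * cam.pixel_um,
            ])
            assert np.abs(got - expect).max() <= 1.5

    def test_opposing_views_dim_opposite_sides(self, quiet_camera):
        """With strong attenuation, a bead deep along view 0's
        illumination axis is dimmed >90% in view 0 but <10% in the
        opposing view."""
        bead = iso.Bead((29.0, 15.0, 15.0), peak=100.0)  # at the +x surface
        ph = iso.Phantom(beads=[bead], bounds_um=((0, 30), (0, 30), (0, 30)))
        psf = iso.PSFModel(3.0, 6.0)
        geom = iso.ScanGeometry(1000.0, 0.0, 0.0, lr_voxel_um=(1.0, 1.0, 3.0))
        att = iso.AttenuationModel(length_scale_um=12.0)
        cam = dataclasses.replace(quiet_camera, pixel_um=1.0)
        seqs = iso.simulate_multiview(ph, psf, geom, cam, attenuation=att,
                                      n_views=8)
        clean = iso.simulate_multiview(ph, psf, geom, cam, n_views=8)
        f0 = seqs[0].frames.sum() / clean[0].frames.sum()
        f4 = seqs[4].frames.sum() / clean[4].frames.sum()
        assert f0 < 0.10
        assert f4 > 0.90
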