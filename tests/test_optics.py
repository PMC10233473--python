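"""Virtual microscope: phantoms, excitation geometry, image formation, noise."""

import math

import numpy as np
import pytest

from tiltsheet.optics import (
    BlinkModel,
    CameraModel,
    ConfigurationError,
    DetectionModel,
    SheetGeometry,
    add_camera_noise,
    field_center_um,
    make_phantom,
    render_frame,
    sheet_excitation,
    simulate_pair,
    simulate_profile_stack,
    simulate_smlm_movie,
)


class TestMakePhantom:
    def test_shell_radii_within_annulus(self):
        ph = make_phantom(
            "shell",
            {"n": 1000, "r_inner_um": 1.5, "r_outer_um": 1.8, "bounds_um": (3, 3, 3)},
            seed=1,
        )
        assert ph.n_emitters == 1000
        r = np.linalg.norm(ph.emitters[:, :3], axis=1)
        assert r.min() >= 1.5 - 1e-12 and r.max() <= 1.8 + 1e-12

    def test_empty_sparse_set(self):
        ph = make_phantom("sparse_molecules", {"n": 0}, seed=0)
        assert ph.n_emitters == 0

    def test_seeded_determinism(self):
        a = make_phantom("dense_volume", {"n": 5000}, seed=7)
        b = make_phantom("dense_volume", {"n": 5000}, seed=7)
        np.testing.assert_array_equal(a.emitters, b.emitters)

    def test_unknown_kind_and_bad_radii(self):
        with pytest.raises(ConfigurationError):
            make_phantom("voronoi", {}, seed=0)
        with pytest.raises(ValueError):
            make_phantom("shell", {"r_outer_um": 9.0, "bounds_um": (3, 3, 3)}, seed=0)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ConfigurationError):
            make_phantom("shell", {"radius": 2.0}, seed=0)


class TestSheetExcitation:
    geom = SheetGeometry(tilt_deg=18.0, waist_fwhm_um=1.25, rayleigh_um=8.0, focus_xy_um=5.0)

    def _point_at(self, d_um, s_um):
        """Sample-space point at perpendicular distance d and in-plane s."""
        th = math.radians(self.geom.tilt_deg)
        x = self.geom.focus_xy_um + s_um * math.cos(th) - d_um * math.sin(th)
        z = s_um * math.sin(th) + d_um * math.cos(th)
        return x, z

    def test_peak_on_midplane_at_focus(self):
        x, z = self._point_at(0.0, 0.0)
        assert sheet_excitation(x, 0.0, z, self.geom) == pytest.approx(1.0)

    def test_half_intensity_at_half_fwhm(self):
        x, z = self._point_at(self.geom.waist_fwhm_um / 2, 0.0)
        assert sheet_excitation(x, 0.0, z, self.geom) == pytest.approx(0.5, rel=1e-9)

    def test_fwhm_grows_sqrt2_at_rayleigh_range(self):
        # numerically locate the half-intensity half-width at s=0 and s=zR
        def half_width(s):
            x0, z0 = self._point_at(0.0, s)
            peak = sheet_excitation(x0, 0.0, z0, self.geom)
            d = np.linspace(0, 4 * self.geom.waist_fwhm_um, 40001)
            pts = [self._point_at(di, s) for di in d]
            prof = np.array([sheet_excitation(x, 0.0, z, self.geom) for x, z in pts])
            return d[np.argmin(np.abs(prof - peak / 2))]

        assert half_width(self.geom.rayleigh_um) / half_width(0.0) == pytest.approx(
            math.sqrt(2.0), rel=1e-3
        )

    def test_symmetric_and_monotone_in_d(self):
        for s in (0.0, 3.0):
            d = np.linspace(0, 3, 50)
            vals = np.array(
                [sheet_excitation(*self._p3(di, s), self.geom) for di in d]
            )
            neg = np.array(
                [sheet_excitation(*self._p3(-di, s), self.geom) for di in d]
            )
            np.testing.assert_allclose(vals, neg, rtol=1e-9)
            assert np.all(np.diff(vals) < 0)

    def _p3(self, d, s):
        x, z = self._point_at(d, s)
        return x, 0.0, z


class TestRenderFrame:
    def test_photon_conservation_many_emitters(self, rng):
        det = DetectionModel(fov_px=(48, 48))
        cx, cy = field_center_um(det)
        pts = np.column_stack(
            [
                rng.uniform(cx - 1.5, cx + 1.5, 100),
                rng.uniform(cy - 1.5, cy + 1.5, 100),
                np.zeros(100),
                rng.uniform(100, 1000, 100),
            ]
        )
        from tiltsheet.optics import Phantom

        ph = Phantom(pts, "sparse_molecules", (cx, cy, 1), (cx, cy, 0))
        img = render_frame(ph, None, det, exposure=2.0, qe=0.8)
        expected = 0.8 * pts[:, 3].sum() * 2.0
        assert img.sum() == pytest.approx(expected, rel=1e-6)

    def test_defocus_widens_psf_per_model(self, det64, center64):
        from tiltsheet.optics import Phantom

        cx, cy = center64
        det = DetectionModel(fov_px=(64, 64), sigma0_nm=130.0, defocus_slope=200.0)
        for z in (0.0, 2.0):
            ph = Phantom([[cx, cy, z, 1000.0]], "sparse_molecules", (cx, cy, 3), (cx, cy, 0))
            img = render_frame(ph, None, det)
            assert img.sum() == pytest.approx(1000.0, rel=1e-6)
            # second-moment estimate of the PSF SD
            yy, xx = np.mgrid[0:64, 0:64]
            x_nm = (xx + 0.5) * det.pixel_nm
            mu = (img * x_nm).sum() / img.sum()
            var = (img * (x_nm - mu) ** 2).sum() / img.sum()
            sd = math.sqrt(var - det.pixel_nm**2 / 12.0)  # deconvolve pixelation
            assert sd == pytest.approx(det.sigma_nm(z), rel=0.02)

    def test_emitter_below_sheet_dark(self, center64):
        from tiltsheet.optics import Phantom

        det = DetectionModel(fov_px=(64, 64))
        cx, cy = field_center_um(det)
        geom = SheetGeometry(18.0, 1.25, 8.0, cx)
        ph = Phantom([[cx, cy, -8.0, 1000.0]], "sparse_molecules", (cx, cy, 9), (cx, cy, 0))
        img_sheet = render_frame(ph, geom, det)
        img_epi = render_frame(ph, None, det)
        assert img_sheet.max() < 1e-6 * img_epi.max()

    def test_empty_phantom_zero_image(self, det64):
        ph = make_phantom("sparse_molecules", {"n": 0}, seed=0)
        assert render_frame(ph, None, det64).sum() == 0.0


class TestCameraNoise:
    def test_zero_signal_gives_offset(self):
        cam = CameraModel(read_noise_counts=0.0)
        img = add_camera_noise(np.zeros((16, 16)), cam, seed=0)
        np.testing.assert_array_equal(img, np.full((16, 16), cam.offset))

    def test_mean_response(self):
        cam = CameraModel(em_gain=50.0, offset=100.0, read_noise_counts=5.0)
        img = add_camera_noise(np.full((400, 250), 100.0), cam, seed=1)
        assert img.mean() == pytest.approx(100.0 + 50.0 * 100.0, rel=0.01)

    def test_excess_noise_doubles_variance(self):
        clean = np.full((600, 600), 100.0)
        lo = add_camera_noise(clean, CameraModel(em_gain=50, read_noise_counts=0, excess_noise=False), 2)
        hi = add_camera_noise(clean, CameraModel(em_gain=50, read_noise_counts=0, excess_noise=True), 2)
        assert hi.var() / lo.var() == pytest.approx(2.0, rel=0.05)

    def test_seeded_determinism_and_negative_rejected(self):
        cam = CameraModel()
        a = add_camera_noise(np.full((8, 8), 5.0), cam, seed=3)
        b = add_camera_noise(np.full((8, 8), 5.0), cam, seed=3)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            add_camera_noise(np.full((4, 4), -1.0), cam, seed=0)


class TestSimulatePair:
    def _pair(self, waist, n_frames=20, seed=5):
        det = DetectionModel(fov_px=(48, 48))
        cam = CameraModel(em_gain=50.0)
        cx, cy = field_center_um(det)
        ph = make_phantom(
            "shell",
            {"n": 300, "center_um": (cx, cy, 0), "bounds_um": (cx, cy, 3), "photon_rate": 80.0},
            seed=11,
        )
        geom = SheetGeometry(18.0, waist, 1e4 if waist > 50 else 8.0, cx)
        return simulate_pair(ph, geom, det, cam, n_frames=n_frames, seed=seed), det, cam

    def test_frame_count_and_shapes(self):
        pair, _, _ = self._pair(1.6, n_frames=100)
        assert pair.epi_stack.shape[0] == 100
        assert pair.epi_stack.shape == pair.sheet_stack.shape

    def test_sheet_mode_rejects_out_of_focus_light(self):
        from tiltsheet.metrics import RoiSpec, annulus_mask, disk_mask, sbr_structure

        pair, det, cam = self._pair(1.6)
        cx_px = det.fov_px[1] / 2 - 0.5
        ring = annulus_mask((48, 48), (cx_px, cx_px), 1.5e3 / 157, 1.9e3 / 157)
        centre = disk_mask((48, 48), (cx_px, cx_px), 0.8e3 / 157)
        roi = RoiSpec(ring, centre)
        sbr_epi = sbr_structure(pair.epi_stack.mean(0) - cam.offset, roi)
        sbr_sheet = sbr_structure(pair.sheet_stack.mean(0) - cam.offset, roi)
        assert sbr_sheet > sbr_epi

    def test_epi_limit_of_thick_orthogonal_sheet(self):
        pair, _, _ = self._pair(100.0)
        geom = pair.geometry
        assert geom.waist_fwhm_um == 100.0
        m_epi = pair.epi_stack.mean(axis=0).mean()
        m_sheet = pair.sheet_stack.mean(axis=0).mean()
        assert abs(m_epi - m_sheet) / m_epi < 0.01


class TestProfileStack:
    def test_default_z_grid_has_41_planes(self):
        geom = SheetGeometry(18.0, 1.25, 8.0, 40.0)
        stack, z = simulate_profile_stack(
            geom, detection=DetectionModel(fov_px=(8, 512)), camera=None
        )
        assert len(z) == 41
        assert z[0] == -10.0 and z[-1] == 10.0 and stack.shape[0] == 41

    def test_vertical_sheet_center_is_z_independent(self):
        from tiltsheet.calibration import fit_profile_1d

        det = DetectionModel(fov_px=(8, 64))
        geom = SheetGeometry(90.0, 1.5, 8.0, 64 * 0.157 / 2)
        stack, z = simulate_profile_stack(geom, -2, 2, 1.0, detection=det, camera=None)
        centers = [
            fit_profile_1d(stack[i].mean(axis=0), axis=(np.arange(64) + 0.5) * 0.157).center
            for i in range(len(z))
        ]
        assert np.ptp(centers) < 0.02  # um

    def test_center_drift_slope_matches_tilt(self):
        from tiltsheet.calibration import estimate_tilt, fit_profile_1d

        det = DetectionModel(fov_px=(8, 832))
        tilt = 18.0
        geom = SheetGeometry(tilt, 1.25, 8.0, 832 * 0.157 / 2)
        stack, z = simulate_profile_stack(geom, detection=det, camera=None)
        centers = []
        for i in range(len(z)):
            fit = fit_profile_1d(stack[i].mean(axis=0), axis=(np.arange(832) + 0.5) * 0.157)
            centers.append(fit.center)
        assert estimate_tilt(np.asarray(centers), z) == pytest.approx(tilt, abs=0.5)

    def test_step_validation(self):
        geom = SheetGeometry(18.0, 1.25, 8.0, 5.0)
        with pytest.raises(ValueError):
            simulate_profile_stack(geom, -1, 1, 5.0)


class TestSMLMMovie:
    def _phantom(self, det, n=30):
        cx, cy = field_center_um(det)
        return make_phantom(
            "sparse_molecules",
            {"n": n, "bounds_um": (0.8 * cx, 0.8 * cy, 0.1), "center_um": (cx, cy, 0)},
            seed=3,
        )

    def test_no_activation_gives_empty_truth(self, det64, camera):
        movie = simulate_smlm_movie(
            self._phantom(det64),
            BlinkModel(on_rate=0.0, off_rate=0.5),
            None,
            det64,
            camera,
            n_frames=10,
            seed=1,
            start_on_prob=0.0,
        )
        assert movie.truth.shape == (0, 4)

    def test_stationary_on_fraction(self, camera):
        det = DetectionModel(fov_px=(16, 16))
        blink = BlinkModel(on_rate=0.2, off_rate=0.6)
        ph = self._phantom(det, n=50)
        movie = simulate_smlm_movie(ph, blink, None, det, camera, n_frames=2000, seed=4)
        frac = len(movie.truth) / (2000 * 50)
        assert frac == pytest.approx(blink.stationary_on, abs=0.01)

    def test_seeded_reproducibility(self, det64, camera):
        kwargs = dict(n_frames=5, seed=9)
        blink = BlinkModel(0.2, 0.5)
        a = simulate_smlm_movie(self._phantom(det64), blink, None, det64, camera, **kwargs)
        b = simulate_smlm_movie(self._phantom(det64), blink, None, det64, camera, **kwargs)
        np.testing.assert_array_equal(a.frames, b.frames)
        np.testing.assert_array_equal(a.truth, b.truth)

    def test_background_shape_validated(self, det64, camera):
        with pytest.raises(ValueError):
            simulate_smlm_movie(
                self._phantom(det64), BlinkModel(), np.zeros((8, 8)), det64, camera, 5, 0
            )
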