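"""Localization pipeline stages: filtering, detection, fitting, post-processing."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.signal import convolve2d

from tiltsheet.optics import (
    BlinkModel,
    CameraModel,
    DetectionModel,
    field_center_um,
    make_phantom,
    simulate_smlm_movie,
)
from tiltsheet.smlm import (
    DetectionConfig,
    denoise_stack,
    detect_peaks,
    drift_correct,
    empty_table,
    evaluate_localizations,
    filter_photons,
    fit_spot_wls,
    remove_duplicates,
    rolling_ball,
    run_pipeline,
    wavelet_f1,
)


def integrated_spot(det, x_nm, y_nm, photons, bg, shape):
    from scipy.special import erf

    h, w = shape
    s = det.sigma0_nm * math.sqrt(2.0)
    xe = np.arange(w + 1) * det.pixel_nm
    ye = np.arange(h + 1) * det.pixel_nm
    fx = 0.5 * erf((xe - x_nm) / s)
    fy = 0.5 * erf((ye - y_nm) / s)
    return photons * np.outer(np.diff(fy), np.diff(fx)) + bg


class TestDenoise:
    def test_none_is_identity(self, rng):
        stack = rng.random((3, 16, 16))
        np.testing.assert_array_equal(denoise_stack(stack, "none"), stack)

    def test_gaussian_smooths_single_frame(self, rng):
        frame = rng.poisson(50.0, (32, 32)).astype(float)
        out = denoise_stack(frame, "gaussian")
        assert out.shape == frame.shape
        assert out.var() < frame.var()

    def test_vst_wavelet_reduces_poisson_variance(self, rng):
        frames = rng.poisson(50.0, (2, 64, 64)).astype(float)
        out = denoise_stack(frames, "vst_wavelet")
        assert out.var() < frames.var()
        assert out.mean() == pytest.approx(50.0, rel=0.05)

    def test_unknown_method(self):
        from tiltsheet.optics import ConfigurationError

        with pytest.raises(ConfigurationError):
            denoise_stack(np.zeros((1, 8, 8)), "bilateral")


class TestRollingBall:
    def test_constant_image_removed_entirely(self):
        out = rolling_ball(np.full((64, 64), 37.0), 50.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_isolated_peaks_preserved(self):
        img = np.full((64, 64), 200.0)
        peaks = [(10, 12), (30, 40), (50, 20)]
        for r, c in peaks:
            img[r - 1 : r + 2, c - 1 : c + 2] += 5000.0
        out = rolling_ball(img, 50.0)
        for r, c in peaks:
            assert out[r, c] == pytest.approx(5000.0, rel=0.05)

    def test_sharp_step_leaves_large_residual(self):
        # the known failure mode near e.g. a nucleolus edge
        img = np.full((64, 64), 100.0)
        img[:, 32:] += 5000.0
        out = rolling_ball(img, 50.0)
        near_step = np.abs(out[:, 30:35]).mean()
        far_field = np.abs(out[:, :10]).mean()
        assert near_step > 10 * max(far_field, 1.0)

    def test_radius_validation(self):
        with pytest.raises(ValueError):
            rolling_ball(np.zeros((32, 32)), 40.0)


class TestWaveletF1:
    def test_constant_image_zero(self):
        np.testing.assert_allclose(wavelet_f1(np.full((32, 32), 9.0)), 0.0, atol=1e-9)

    def test_impulse_response_matches_direct_convolution(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        k1 = np.array([1, 4, 6, 4, 1]) / 16.0
        k2 = np.zeros(9)
        k2[::2] = k1
        K1 = np.outer(k1, k1)
        K2 = np.outer(k2, k2)
        v1 = convolve2d(img, K1, mode="same")
        v2 = convolve2d(v1, K2, mode="same")
        np.testing.assert_allclose(wavelet_f1(img), v1 - v2, atol=1e-12)

    def test_linear_ramp_interior_annihilated(self):
        yy, xx = np.mgrid[0:64, 0:64]
        ramp = 3.0 * xx + 2.0 * yy
        f1 = wavelet_f1(ramp)
        assert np.abs(f1[8:-8, 8:-8]).max() < 1e-9 * np.ptp(ramp)


class TestDetectPeaks:
    def test_flat_frame_no_candidates(self):
        assert detect_peaks(np.full((32, 32), 5.0), 4.0) == []

    def test_single_bright_spot_single_candidate(self, rng):
        img = rng.normal(0, 1.0, (64, 64))
        img[30, 40] += 50.0
        peaks = detect_peaks(img, 4.0)
        assert peaks == [(30, 40)]

    def test_monotone_in_threshold(self, rng):
        img = rng.normal(0, 1.0, (64, 64))
        for r, c in [(10, 10), (30, 40), (50, 20)]:
            img[r, c] += rng.uniform(5, 50)
        counts = [len(detect_peaks(img, k)) for k in (1.0, 2.0, 4.0, 8.0, 1e6)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 0

    def test_plateau_counted_once_lexicographic(self):
        img = np.zeros((16, 16))
        img[5, 5] = img[5, 6] = 10.0  # two-pixel plateau
        assert detect_peaks(img, 1.0) == [(5, 5)]


class TestFitSpotWls:
    det = DetectionModel(fov_px=(21, 21))

    def test_noiseless_subpixel_recovery_within_1nm(self):
        x_nm, y_nm = 10.37 * 157.0, 9.81 * 157.0
        img = integrated_spot(self.det, x_nm, y_nm, 1000.0, 2.0, (21, 21))
        rec = fit_spot_wls(img, (10, 10), 4, self.det)
        assert rec is not None
        assert rec["x_nm"] == pytest.approx(x_nm, abs=1.0)
        assert rec["y_nm"] == pytest.approx(y_nm, abs=1.0)
        assert rec["photons"] == pytest.approx(1000.0, rel=1e-3)

    def test_photon_estimate_monte_carlo(self):
        x_nm = y_nm = 10.5 * 157.0
        clean = integrated_spot(self.det, x_nm, y_nm, 1000.0, 5.0, (21, 21))
        photons = []
        for seed in range(100):
            noisy = np.random.default_rng(seed).poisson(clean).astype(float)
            rec = fit_spot_wls(noisy, (10, 10), 4, self.det)
            if rec:
                photons.append(rec["photons"])
        assert np.mean(photons) == pytest.approx(1000.0, rel=0.05)

    def test_border_candidate_rejected(self):
        img = np.ones((21, 21))
        assert fit_spot_wls(img, (1, 10), 4, self.det) is None

    def test_width_gate_rejects_flat_window(self, rng):
        img = rng.normal(100.0, 0.1, (21, 21))
        assert fit_spot_wls(img, (10, 10), 4, self.det) is None


class TestFilterPhotons:
    def test_inclusive_bounds_count(self):
        t = pd.DataFrame(
            {"id": range(5), "frame": 0, "photons": [100.0, 500.0, 1500.0, 2500.0, 3000.0]}
        )
        out = filter_photons(t, 500, 2500)
        assert sorted(out["photons"]) == [500.0, 1500.0, 2500.0]

    def test_empty_and_identity(self):
        assert filter_photons(empty_table(), 500, 2500).empty
        t = pd.DataFrame({"id": [0], "frame": [0], "photons": [42.0]})
        assert len(filter_photons(t, 0, np.inf)) == 1

    def test_idempotent(self, rng):
        t = pd.DataFrame(
            {"id": range(50), "frame": 0, "photons": rng.uniform(0, 4000, 50)}
        )
        once = filter_photons(t, 500, 2500)
        twice = filter_photons(once, 500, 2500)
        pd.testing.assert_frame_equal(once, twice)


def clustered_table(rng, n=3000, n_frames=400):
    frames = rng.integers(0, n_frames, n)
    cx = rng.uniform(500, 9500, 30)
    cy = rng.uniform(500, 9500, 30)
    pick = rng.integers(0, 30, n)
    x = cx[pick] + rng.normal(0, 40, n)
    y = cy[pick] + rng.normal(0, 40, n)
    return frames, x, y


class TestDriftCorrect:
    def test_null_drift_below_one_bin(self):
        rng = np.random.default_rng(0)
        frames, x, y = clustered_table(rng)
        t = pd.DataFrame({"id": range(len(x)), "frame": frames, "x_nm": x, "y_nm": y, "photons": 1000.0})
        _, trace = drift_correct(t, 5, 5, 157.0)
        assert np.nanmax(np.abs(trace[["dx_nm", "dy_nm"]].to_numpy())) < 157.0 / 5
    def test_linear_drift_recovered(self):
        rng = np.random.default_rng(1)
        frames, x, y = clustered_table(rng)
        rate = 100.0 / 399
        t = pd.DataFrame(
            {
                "id": range(len(x)),
                "frame": frames,
                "x_nm": x + frames * rate,
                "y_nm": y,
                "photons": 1000.0,
            }
        )
        corrected, _ = drift_correct(t, 5, 5, 157.0)
        residual = corrected["x_nm"].to_numpy() - x
        residual -= residual.mean()  # correction is relative to the first bin
        assert np.sqrt(np.mean(residual**2)) < 10.0

    def test_first_bin_is_reference(self):
        rng = np.random.default_rng(2)
        frames, x, y = clustered_table(rng)
        t = pd.DataFrame({"id": range(len(x)), "frame": frames, "x_nm": x, "y_nm": y, "photons": 1000.0})
        _, trace = drift_correct(t, 4, 5, 157.0)
        assert trace.loc[0, "dx_nm"] == 0.0 and trace.loc[0, "dy_nm"] == 0.0

    def test_span_validation(self):
        t = pd.DataFrame({"id": [0, 1], "frame": [0, 1], "x_nm": [0.0, 1.0], "y_nm": [0.0, 1.0], "photons": [1.0, 1.0]})
        with pytest.raises(ValueError):
            drift_correct(t, 5, 5)


class TestRemoveDuplicates:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["id", "frame", "x_nm", "y_nm", "photons"]
        )

    def test_close_pair_keeps_brighter(self):
        t = self._table([[0, 0, 100.0, 100.0, 800.0], [1, 0, 115.0, 100.0, 600.0]])
        out = remove_duplicates(t, 30.0)
        assert len(out) == 1 and out.iloc[0]["photons"] == 800.0

    def test_distant_pair_kept(self):
        t = self._table([[0, 0, 100.0, 100.0, 800.0], [1, 0, 140.0, 100.0, 600.0]])
        assert len(remove_duplicates(t, 30.0)) == 2

    def test_same_position_different_frames_kept(self):
        t = self._table([[0, 0, 100.0, 100.0, 800.0], [1, 1, 100.0, 100.0, 800.0]])
        assert len(remove_duplicates(t, 30.0)) == 2

    def test_no_close_pair_survives(self, rng):
        rows = [
            [i, int(rng.integers(0, 3)), rng.uniform(0, 500), rng.uniform(0, 500), rng.uniform(100, 1000)]
            for i in range(120)
        ]
        out = remove_duplicates(self._table(rows), 30.0)
        for _, sub in out.groupby("frame"):
            pts = sub[["x_nm", "y_nm"]].to_numpy()
            if len(pts) > 1:
                from scipy.spatial.distance import pdist

                assert pdist(pts).min() >= 30.0


class TestEvaluateLocalizations:
    def _truth(self, rng, n=200):
        return np.column_stack(
            [
                rng.integers(0, 20, n),
                rng.uniform(0, 10000, n),
                rng.uniform(0, 10000, n),
                np.full(n, 1000.0),
            ]
        ).astype(float)

    def test_perfect_table(self, rng):
        truth = self._truth(rng)
        table = pd.DataFrame(
            {
                "id": range(len(truth)),
                "frame": truth[:, 0],
                "x_nm": truth[:, 1],
                "y_nm": truth[:, 2],
                "photons": truth[:, 3],
            }
        )
        res = evaluate_localizations(table, truth, 100.0)
        assert res.recall == 1.0 and res.precision == 1.0 and res.rmse_nm == 0.0

    def test_isotropic_jitter_rmse(self, rng):
        truth = self._truth(rng, 3000)
        table = pd.DataFrame(
            {
                "id": range(len(truth)),
                "frame": truth[:, 0],
                "x_nm": truth[:, 1] + rng.normal(0, 50, len(truth)),
                "y_nm": truth[:, 2] + rng.normal(0, 50, len(truth)),
                "photons": truth[:, 3],
            }
        )
        res = evaluate_localizations(table, truth, 300.0)
        assert res.recall > 0.98
        assert res.rmse_nm == pytest.approx(50.0 * math.sqrt(2.0), rel=0.05)

    def test_empty_table_and_truth(self, rng):
        truth = self._truth(rng, 10)
        res = evaluate_localizations(empty_table(), truth, 100.0)
        assert res.recall == 0.0 and "empty_table" in res.flags
        res2 = evaluate_localizations(empty_table(), truth[:0], 100.0)
        assert math.isnan(res2.recall) and "empty_truth" in res2.flags


@pytest.fixture(scope="module")
def movie():
    det = DetectionModel(fov_px=(64, 64))
    cam = CameraModel()
    cx, cy = field_center_um(det)
    ph = make_phantom(
        "sparse_molecules",
        {
            "n": 15,
            "bounds_um": (0.75 * cx, 0.75 * cy, 0.05),
            "center_um": (cx, cy, 0.0),
            "photon_rate": 1000.0,
            "min_sep_um": 0.8,  # resolvable single-emitter regime
        },
        seed=5,
    )
    return simulate_smlm_movie(
        ph, BlinkModel(1.0, 0.0), None, det, cam, n_frames=8, seed=6, start_on_prob=1.0
    )

class TestRunPipeline:
    def test_deterministic(self, movie):
        cfg = DetectionConfig(drift_bins=2)
        a = run_pipeline(movie, "none", config=cfg)
        b = run_pipeline(movie, "none", config=cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_background_free_modes_agree(self, movie):
        cfg = DetectionConfig(drift_bins=2)
        t_none = run_pipeline(movie, "none", config=cfg)
        t_rb = run_pipeline(movie, "rolling_ball", config=cfg)
        assert abs(len(t_none) - len(t_rb)) <= 0.05 * len(t_none)

    def test_recall_on_flat_background(self, movie):
        table = run_pipeline(movie, "none", config=DetectionConfig(drift_bins=2))
        res = evaluate_localizations(table, movie.truth, 100.0)
        assert res.recall >= 0.9

    def test_model_mode_requires_model(self, movie):
        from tiltsheet.optics import ConfigurationError

        with pytest.raises(ConfigurationError):
            run_pipeline(movie, "model", model=None)
        with pytest.raises(ConfigurationError):
            run_pipeline(movie, "median", model=None)
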