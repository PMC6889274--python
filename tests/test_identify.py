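"""Pre-processing, matched-filter detection and the significance metric."""

import numpy as np
import pandas as pd
import pytest

from scmosfit import (
    CalibrationMap,
    SimulationConfig,
    detection_bias_report,
    expected_significance,
    find_candidates,
    find_candidates_movie,
    gaussian_tail_probability,
    make_emitters,
    preprocess,
    simulate_movie,
    smooth_map,
)
from scmosfit.identify import PreprocessedFrame, aperture_significance


class TestPreprocess:
    def test_electron_conversion(self, uniform_camera):
        raw = np.full(uniform_camera.shape, 200.0)
        pre = preprocess(raw, uniform_camera, "none")
        assert np.allclose(pre.values, 50.0)  # (200-100)/2

    def test_rqe_mode(self):
        calib = CalibrationMap.uniform((4, 4), offset=100.0, gain=2.0, rqe=0.8)
        pre = preprocess(np.full((4, 4), 200.0), calib, "rqe")
        assert np.allclose(pre.values, 62.5)  # (200-100)/(2*0.8)

    def test_rqe_unity_identical_to_plain(self, striped_camera):
        calib = CalibrationMap(
            offset=striped_camera.offset,
            variance=striped_camera.variance,
            gain=striped_camera.gain,
            rqe=np.ones(striped_camera.shape),
        )
        raw = np.full(striped_camera.shape, 500.0)
        a = preprocess(raw, calib, "none").values
        b = preprocess(raw, calib, "rqe").values
        assert np.array_equal(a, b)

    def test_bad_mode(self, uniform_camera):
        with pytest.raises(ValueError, match="mode"):
            preprocess(np.zeros(uniform_camera.shape), uniform_camera, "flat")


class TestSmoothMap:
    def test_constant_preserved(self):
        assert np.allclose(smooth_map(np.full((16, 16), 3.3), 1.5), 3.3)

    def test_impulse_normalized(self):
        img = np.zeros((31, 31))
        img[15, 15] = 1.0
        assert smooth_map(img, 1.5).sum() == pytest.approx(1.0, rel=1e-6)

    def test_smoothing_contracts_variance(self, striped_camera):
        raw_std = striped_camera.rqe.std()
        assert smooth_map(striped_camera.rqe, 1.5).std() < raw_std


class TestSignificance:
    def test_six_sigma_tail_probability(self):
        assert gaussian_tail_probability(6.0) == pytest.approx(2.0e-9, rel=0.02)

    def test_direct_definition(self):
        # 60 e- signal over a 100 e- background aperture -> 6 sigma; build
        # a frame whose disk sum minus background matches exactly
        sigma = 1.5
        from scmosfit.identify import _aperture_masks

        disk, annulus, half = _aperture_masks(sigma)
        n_disk = int(disk.sum())
        bg = 100.0 / n_disk  # background e- per pixel so disk holds 100 e-
        frame = np.full((2 * half + 1 + 8, 2 * half + 1 + 8, ), bg)
        c = frame.shape[0] // 2
        window = frame[c - half : c + half + 1, c - half : c + half + 1]
        window[disk] += 60.0 / n_disk  # spread 60 e- uniformly over the disk
        sig = aperture_significance(frame, np.array([c]), np.array([c]), sigma)
        assert sig[0] == pytest.approx(6.0, rel=1e-9)

    def test_disk_significance_with_known_background(self):
        # supplying the exact background reproduces the aperture value
        # without the annulus estimate
        from scmosfit.identify import _aperture_masks, disk_significance

        sigma = 1.5
        disk, _, half = _aperture_masks(sigma)
        n_disk = int(disk.sum())
        frame = np.full((2 * half + 9, 2 * half + 9), 5.0)
        c = frame.shape[0] // 2
        frame[c - half : c + half + 1, c - half : c + half + 1][disk] += 60.0 / n_disk
        sig = disk_significance(
            frame, np.array([c]), np.array([c]), np.array([5.0]), sigma
        )
        assert sig[0] == pytest.approx(60.0 / np.sqrt(5.0 * n_disk), rel=1e-9)

    def test_expected_significance_linear_in_photons(self):
        # the background (hence the noise) is fixed, so the expected
        # significance is linear in the emitter intensity
        lo = expected_significance(100.0, 20.0, 1.5)
        hi = expected_significance(400.0, 20.0, 1.5)
        assert hi == pytest.approx(4 * lo, rel=1e-9)


class TestFindCandidates:
    def test_flat_frame_has_no_candidates(self, uniform_camera):
        pre = PreprocessedFrame(np.full(uniform_camera.shape, 20.0), "none")
        cands = find_candidates(pre, 1.5, 1.0)
        assert len(cands) == 0

    def test_single_emitter_found_at_peak(self, uniform_camera):
        cfg = SimulationConfig(n_frames=1, photons_per_frame=2000.0,
                               grid_margin_px=32, grid_spacing_px=64,
                               grid_subpixel_jitter=False)
        em = make_emitters("constant-grid", uniform_camera.shape, cfg, seed=0)
        movie = simulate_movie(em, uniform_camera, cfg, seed=1)
        pre = preprocess(movie.frames[0], uniform_camera, "none")
        cands = find_candidates(pre, 1.5, 6.0)
        assert len(cands) == 1
        assert abs(cands["row"][0] - 32) <= 1 and abs(cands["col"][0] - 32) <= 1
        assert cands["significance"][0] > 20

    def test_duplicate_suppression(self, uniform_camera):
        # two maxima closer than 2 sigma collapse to one candidate
        pre_vals = np.full(uniform_camera.shape, 20.0)
        for r, c, amp in ((30, 30, 30.0), (31, 31, 25.0)):
            yy, xx = np.mgrid[0:64, 0:64]
            pre_vals = pre_vals + amp * np.exp(
                -((xx - c) ** 2 + (yy - r) ** 2) / (2 * 1.5**2)
            )
        cands = find_candidates(PreprocessedFrame(pre_vals, "none"), 1.5, 3.0)
        assert len(cands) == 1

    def test_movie_scan_annotates_smoothed_maps(self, striped_camera):
        cfg = SimulationConfig(n_frames=3, photons_per_frame=2000.0,
                               grid_margin_px=24, grid_spacing_px=48)
        em = make_emitters("constant-grid", striped_camera.shape, cfg, seed=2)
        movie = simulate_movie(em, striped_camera, cfg, seed=3)
        cands = find_candidates_movie(movie.frames, striped_camera, "rqe", 1.5, 6.0)
        assert {"smoothed_rqe", "smoothed_gain"}.issubset(cands.columns)
        assert len(cands) >= 2 * em.n_emitters  # most emitters in most frames


class TestBiasReport:
    def _toy_locs(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "row": rng.integers(8, 56, n),
                "col": rng.integers(8, 56, n),
                "significance": rng.normal(8.0, 1.0, n),
            }
        )

    def test_pure_function(self, striped_camera):
        locs = self._toy_locs()
        sub = striped_camera.crop(0, 64, 0, 64)
        a = detection_bias_report(locs, sub, 1.5)
        b = detection_bias_report(locs, sub, 1.5)
        assert a["discard_fraction_high"] == b["discard_fraction_high"]
        assert np.array_equal(a["histogram_high"], b["histogram_high"])

    def test_unbiased_significance_gives_equal_categories(self, striped_camera):
        # significance independent of position: both categories discard ~50%
        locs = self._toy_locs(n=6000)
        sub = striped_camera.crop(0, 64, 0, 64)
        rep = detection_bias_report(locs, sub, 1.5)
        assert abs(rep["discard_fraction_high"] - 0.5) < 0.06
        assert abs(rep["discard_fraction_low"] - 0.5) < 0.06
        assert rep["ks_pvalue"] > 0.01

    def test_empty_input_warns(self, striped_camera):
        with pytest.warns(UserWarning, match="empty"):
            rep = detection_bias_report(
                pd.DataFrame(columns=["row", "col", "significance"]), striped_camera, 1.5
            )
        assert rep["n_low"] == 0 and rep["n_high"] == 0

    def test_bad_quantile(self, striped_camera):
        with pytest.raises(ValueError, match="quantile"):
            detection_bias_report(self._toy_locs(), striped_camera, 1.5, quantile=0.7)
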