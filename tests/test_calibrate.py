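"""Photon-transfer calibration: offset/variance, gain fit, RQE recovery."""

import numpy as np
import pytest

from scmosfit import (
    CameraMovie,
    IlluminationSeries,
    calibrate_camera,
    compute_offset_variance,
    compute_rqe,
    fit_gain,
    lamp_corrected_stats,
    simulate_illumination_series,
    synth_calibration,
)


class TestOffsetVariance:
    def test_constant_signal(self):
        movie = CameraMovie(np.full((5, 4, 4), 100.0))
        offset, var = compute_offset_variance(movie)
        assert np.allclose(offset, 100.0)
        assert np.allclose(var, 0.0)

    def test_two_frame_population_variance(self):
        # divisor-M variance: [99, 101] -> mean 100, variance 1
        frames = np.stack([np.full((2, 2), 99.0), np.full((2, 2), 101.0)])
        offset, var = compute_offset_variance(CameraMovie(frames))
        assert np.allclose(offset, 100.0)
        assert np.allclose(var, 1.0)

    def test_gaussian_noise_recovery(self, rng):
        frames = rng.normal(100.0, 2.0, size=(20000, 8, 8))
        offset, var = compute_offset_variance(CameraMovie(frames))
        assert np.all(np.abs(offset - 100.0) < 0.1)
        assert np.all(np.abs(var - 4.0) < 0.2)

    def test_population_form_matches_direct_sum(self, rng):
        frames = rng.normal(50.0, 3.0, size=(64, 6, 6))
        offset, var = compute_offset_variance(CameraMovie(frames))
        direct = ((frames - offset) ** 2).mean(axis=0)
        assert np.allclose(var, direct, rtol=1e-9, atol=1e-9)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            compute_offset_variance(CameraMovie(np.zeros((1, 4, 4))))

    def test_non_finite_rejected(self):
        frames = np.zeros((3, 2, 2))
        frames[1, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            CameraMovie(frames)


class TestLampCorrection:
    def test_flicker_removed_for_uniform_scene(self, rng):
        # a constant image scaled by per-frame factors: after subtracting the
        # variance of the frame-average, a uniform pixel's variance ~ 0
        scale = 1.0 + 0.01 * rng.standard_normal(4000)
        frames = scale[:, None, None] * np.full((1, 6, 6), 1000.0)
        movie = CameraMovie(frames)
        raw_var = frames.var(axis=0)
        mean, var, _ = lamp_corrected_stats(movie, np.zeros((6, 6)), np.zeros((6, 6)))
        assert raw_var.mean() > 50.0
        assert np.all(var < 0.05 * raw_var)
        assert np.allclose(mean, frames.mean(axis=0), rtol=1e-12)

    def test_stable_lamp_is_plain_dark_subtraction(self):
        frames = np.stack([np.full((3, 3), 150.0), np.full((3, 3), 152.0)])
        dark_offset = np.full((3, 3), 100.0)
        dark_var = np.full((3, 3), 0.5)
        mean, var, _ = lamp_corrected_stats(CameraMovie(frames), dark_offset, dark_var)
        # frame means move together -> lamp term equals the pixel variance here
        assert np.allclose(mean, 51.0)
        assert np.all(var >= 0.0)

    def test_poisson_gain_movie_moments(self, rng):
        # gain 2, 100 e- expectation, offset 100: corrected mean ~ 200, var ~ 400
        n = 20000
        frames = 100.0 + 2.0 * rng.poisson(100.0, size=(n, 8, 8))
        mean, var, _ = lamp_corrected_stats(
            CameraMovie(frames.astype(float)), np.full((8, 8), 100.0), np.zeros((8, 8))
        )
        assert np.all(np.abs(mean - 200.0) < 1.0)
        assert np.all(np.abs(var - 400.0) < 30.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            lamp_corrected_stats(
                CameraMovie(np.zeros((3, 4, 4))), np.zeros((5, 5)), np.zeros((5, 5))
            )


class TestGainFit:
    def test_exact_line_through_origin(self):
        shape = (3, 3)
        stats = [
            (np.full(shape, 100.0), np.full(shape, 200.0)),
            (np.full(shape, 200.0), np.full(shape, 400.0)),
        ]
        gain, intercept = fit_gain(stats)
        assert np.allclose(gain, 2.0)
        assert np.allclose(intercept, 0.0, atol=1e-9)

    def test_single_level_two_point_line(self):
        gain, _ = fit_gain([(np.full((2, 2), 50.0), np.full((2, 2), 100.0))])
        assert np.allclose(gain, 2.0)

    def test_matches_normal_equations_oracle(self, rng):
        # independently coded least squares on the same (K+1)-point system
        k = 4
        means = [rng.uniform(50, 500, size=(5, 5)) for _ in range(k)]
        varis = [2.3 * m + 5.0 + rng.normal(0, 5, size=(5, 5)) for m in means]
        gain, intercept = fit_gain(list(zip(means, varis)))
        for i in range(5):
            for j in range(5):
                xs = np.array([m[i, j] for m in means] + [0.0])
                ys = np.array([v[i, j] for v in varis] + [0.0])
                a = np.vstack([xs, np.ones_like(xs)]).T
                slope, icept = np.linalg.lstsq(a, ys, rcond=None)[0]
                assert gain[i, j] == pytest.approx(slope, rel=1e-9)
                assert intercept[i, j] == pytest.approx(icept, rel=1e-6, abs=1e-6)

    def test_no_levels_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            fit_gain([])

    def test_degenerate_abscissa_flagged(self):
        stats = [
            (np.zeros((2, 2)), np.full((2, 2), 10.0)),
            (np.zeros((2, 2)), np.full((2, 2), 20.0)),
        ]
        with pytest.warns(UserWarning, match="degenerate"):
            gain, _ = fit_gain(stats)
        assert np.all(np.isnan(gain))


class TestRQE:
    def test_uniform_image_gives_unit_rqe(self):
        frames = np.full((3, 20, 20), 500.0)
        rqe = compute_rqe(CameraMovie(frames), np.zeros((20, 20)), np.ones((20, 20)))
        assert np.allclose(rqe, 1.0)

    def test_single_hot_pixel_hand_convolution(self):
        # a pixel 4% above its neighbors enters its own 10x10 window at
        # weight 1/100: rqe = 1.04 / (1 + 0.04/100)
        img = np.full((40, 40), 1000.0)
        img[20, 20] *= 1.04
        frames = np.broadcast_to(img, (2, 40, 40))
        rqe = compute_rqe(CameraMovie(frames), np.zeros((40, 40)), np.ones((40, 40)))
        assert rqe[20, 20] == pytest.approx(1.04 / (1 + 0.04 / 100), rel=1e-9)

    def test_low_illumination_rejected(self):
        frames = np.full((2, 12, 12), 90.0)  # below offset
        with pytest.raises(ValueError, match="non-positive"):
            compute_rqe(CameraMovie(frames), np.full((12, 12), 100.0), np.ones((12, 12)))

    def test_local_mean_is_unity(self, striped_camera, rng):
        # recovered RQE from a simulated bright movie has 10x10 block means ~ 1
        series = simulate_illumination_series(
            striped_camera, n_frames=100, level_fractions=(1.0,), seed=rng
        )
        offset, var = compute_offset_variance(series.dark)
        rqe = compute_rqe(series.levels[0], offset, striped_camera.gain)
        blocks = rqe[8:88, 8:88].reshape(8, 10, 8, 10).mean(axis=(1, 3))
        assert np.all(blocks > 0.98) and np.all(blocks < 1.02)


class TestFullCalibration:
    @pytest.fixture(scope="class")
    def recovered(self):
        truth = synth_calibration((48, 48), seed=5)
        series = simulate_illumination_series(
            truth, n_frames=3000, max_expectation_e=2000.0,
            lamp_flicker_frac=0.01, seed=6,
        )
        return truth, calibrate_camera(series)

    def test_round_trip_offset_variance(self, recovered):
        truth, est = recovered
        # offset error ~ sigma/sqrt(M)
        sigma = np.sqrt(truth.variance)
        assert np.all(np.abs(est.offset - truth.offset) < 5 * sigma / np.sqrt(3000) + 1e-6)
        assert np.abs(est.variance.mean() - truth.variance.mean()) < 0.5

    def test_round_trip_gain_and_rqe(self, recovered):
        truth, est = recovered
        # per-pixel slope error ~ sqrt(2/M); at M=3000 that is ~2%,
        # and the RQE error is dominated by the propagated gain error
        rel_gain = np.abs(est.gain - truth.gain) / truth.gain
        assert np.mean(rel_gain) < 0.03
        rms_rqe = np.sqrt(np.mean((est.rqe - truth.rqe) ** 2))
        assert rms_rqe < 0.035

    def test_anti_correlation_recovered(self, recovered):
        truth, est = recovered
        assert truth.summary()["gain_rqe_correlation"] < -0.5
        assert est.summary()["gain_rqe_correlation"] < -0.5

    def test_errors_shrink_with_frames(self):
        truth = synth_calibration((32, 32), seed=9)
        errs = []
        for m in (400, 3600):
            series = simulate_illumination_series(truth, n_frames=m, seed=m)
            est = calibrate_camera(series)
            errs.append(np.sqrt(np.mean((est.gain - truth.gain) ** 2)))
        # 9x more frames -> errors ~ 3x smaller
        assert errs[1] < errs[0] / 1.8

    def test_dark_only_rejected(self, rng):
        dark = CameraMovie(rng.normal(100, 2, size=(10, 8, 8)))
        with pytest.raises(ValueError, match="at least one"):
            calibrate_camera(IlluminationSeries(dark=dark, levels=[]))
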