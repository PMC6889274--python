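"""Estimator terms, the Poisson deviance, and Levenberg-Marquardt fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scmosfit import (
    CalibrationMap,
    FitOptions,
    SimulationConfig,
    batch_fit,
    build_terms,
    chi2_mle,
    fit_at_positions,
    fit_emitter,
    fit_rois,
    make_emitters,
    render_expectation,
    significance_from_fit,
    simulate_movie,
)
from scmosfit.psf import psf_values, psf_values_and_jacobian, roi_grid


class TestChi2:
    def test_perfect_fit_is_zero(self):
        x = np.array([1.0, 2.5, 7.0])
        assert chi2_mle(x, x) == 0.0

    def test_hand_computed_value(self):
        # 2(2-1) - 2*1*ln 2
        assert chi2_mle([2.0], [1.0]) == pytest.approx(2 - 2 * np.log(2), rel=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(0.01, 1e4), min_size=1, max_size=10),
        st.lists(st.floats(0.01, 1e4), min_size=1, max_size=10),
    )
    def test_deviance_non_negative(self, f, x):
        n = min(len(f), len(x))
        assert chi2_mle(f[:n], x[:n]) >= -1e-9

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            chi2_mle([0.0], [1.0])


class TestPsfModel:
    def test_jacobian_matches_finite_differences(self):
        xg, yg = roi_grid((11, 11))
        for model in ("integrated", "sampled"):
            theta = np.array([15.0, 5.3, 4.8, 2.0, 1.4])
            val, jac = psf_values_and_jacobian(theta, xg, yg, model=model)
            eps = 1e-6
            for p in range(5):
                tp = theta.copy()
                tp[p] += eps
                tm = theta.copy()
                tm[p] -= eps
                num = (
                    psf_values(tp, xg, yg, model=model)
                    - psf_values(tm, xg, yg, model=model)
                ) / (2 * eps)
                assert np.allclose(jac[p], num, rtol=1e-5, atol=1e-7), (model, p)

    def test_integrated_mass_equals_total_photons(self):
        xg, yg = roi_grid((41, 41))
        height = 250.0 / (2 * np.pi * 1.5**2)
        vals = psf_values(np.array([height, 20.0, 20.0, 0.0]), xg, yg, sigma=1.5,
                          model="integrated")
        assert vals.sum() == pytest.approx(250.0, rel=1e-6)


class TestBuildTerms:
    def _roi(self, value=120.0, side=5):
        raw = np.full((side, side), value)
        calib = {
            "offset": np.full((side, side), 100.0),
            "gain": np.full((side, side), 2.0),
            "rqe": np.full((side, side), 1.0),
            "variance": np.full((side, side), 0.0),
        }
        return raw, calib

    def test_uniform_camera_wls_reduces_to_electron_conversion(self):
        raw, calib = self._roi()
        theta = np.array([1.0, 2.0, 2.0, 5.0])
        f, x, w = build_terms(raw, calib, theta, "wls")
        # flat_i * <g> = g * rqe = 2: x = (raw - o)/2 = 10 e-
        assert np.allclose(x, 10.0)

    def test_rqe_unity_makes_mle_terms_identical(self):
        raw, calib = self._roi()
        calib["variance"][:] = 8.0
        theta = np.array([3.0, 2.0, 2.0, 1.0])
        f1, x1 = build_terms(raw, calib, theta, "mle")
        f2, x2 = build_terms(raw, calib, theta, "mle-rqe")
        assert np.array_equal(f1, f2) and np.array_equal(x1, x2)

    def test_zero_read_noise_rqe_scaling(self):
        raw, calib = self._roi()
        calib["rqe"] = np.full((5, 5), 0.9)
        theta = np.array([3.0, 2.0, 2.0, 1.0])
        f, x = build_terms(raw, calib, theta, "mle-rqe")
        f_ref, _ = build_terms(raw, self._roi()[1], theta, "mle")
        assert np.allclose(f, 0.9 * f_ref)
        assert np.allclose(x, 10.0)  # data conversion ignores rqe for MLE forms

    def test_unknown_estimator(self):
        raw, calib = self._roi()
        with pytest.raises(ValueError, match="estimator"):
            build_terms(raw, calib, np.zeros(4), "huber")


def _noise_free_roi(theta, side=11, sigma=1.5, rqe=1.0, gain=2.0, offset=100.0):
    xg, yg = roi_grid((side, side))
    f = psf_values(np.asarray(theta), xg, yg, sigma=sigma, model="integrated")
    raw = (rqe * f).reshape(side, side) * gain + offset
    calib = {
        "offset": np.full((side, side), offset),
        "gain": np.full((side, side), gain),
        "rqe": np.full((side, side), rqe),
        "variance": np.full((side, side), 0.0),
    }
    return raw, calib


class TestFitting:
    @pytest.mark.parametrize("estimator", ["mle", "mle-rqe", "wls"])
    def test_noise_free_recovery(self, estimator):
        truth = np.array([18.0, 5.3, 4.6, 3.0])
        raw, calib = _noise_free_roi(truth)
        start = truth + np.array([2.0, 0.3, -0.3, 1.0])
        res = fit_emitter(raw, calib, start, estimator)
        assert res["converged"]
        assert np.allclose(res["theta"][1:3], truth[1:3], atol=1e-6)
        assert np.allclose(res["theta"][[0, 3]], truth[[0, 3]], rtol=1e-4)

    def test_estimators_agree_on_uniform_noise_free_data(self):
        truth = np.array([18.0, 5.1, 5.7, 3.0])
        raw, calib = _noise_free_roi(truth)
        thetas = [
            fit_emitter(raw, calib, None, est)["theta"] for est in ("mle", "mle-rqe", "wls")
        ]
        for t in thetas[1:]:
            assert np.allclose(t, thetas[0], atol=1e-4)

    def test_free_sigma_recovery(self):
        sigma_true = 1.8
        truth = np.array([18.0, 5.3, 4.6, 3.0, sigma_true])
        xg, yg = roi_grid((11, 11))
        f = psf_values(truth, xg, yg, model="integrated")
        raw = f.reshape(11, 11) * 2.0 + 100.0
        calib = {k: np.full((11, 11), v) for k, v in
                 [("offset", 100.0), ("gain", 2.0), ("rqe", 1.0), ("variance", 0.0)]}
        opts = FitOptions(free_sigma=True)
        res = fit_emitter(raw, calib, np.array([15.0, 5.0, 5.0, 2.0, 1.5]), "mle", opts)
        assert res["converged"]
        assert res["theta"][4] == pytest.approx(sigma_true, abs=1e-4)

    def test_batch_matches_single(self, rng):
        truth = np.array([18.0, 5.3, 4.6, 3.0])
        raw, calib = _noise_free_roi(truth)
        raw_noisy = raw + rng.normal(0, 1.0, raw.shape)
        batch = fit_rois(
            np.stack([raw_noisy] * 3),
            {k: np.stack([v] * 3) for k, v in calib.items()},
            "mle",
        )
        single = fit_emitter(raw_noisy, calib, None, "mle")
        for i in range(3):
            assert np.allclose(batch["theta"][i], single["theta"])

    def test_determinism(self, striped_camera):
        cfg = SimulationConfig(n_frames=4, rng_seed=0)
        em = make_emitters("constant-grid", striped_camera.shape,
                           cfg.with_(grid_margin_px=12, grid_spacing_px=24), seed=5)
        movie = simulate_movie(em, striped_camera, cfg, seed=6)
        a = fit_at_positions(movie, striped_camera, em.positions, "mle-rqe")
        b = fit_at_positions(movie, striped_camera, em.positions, "mle-rqe")
        assert a.drop(columns="estimator").equals(b.drop(columns="estimator"))

    def test_convergence_fraction_high(self, striped_camera):
        cfg = SimulationConfig(n_frames=30, rng_seed=0)
        em = make_emitters("constant-grid", striped_camera.shape,
                           cfg.with_(grid_margin_px=12, grid_spacing_px=24), seed=5)
        movie = simulate_movie(em, striped_camera, cfg, seed=6)
        table = fit_at_positions(movie, striped_camera, em.positions, "mle-rqe")
        assert table.attrs["convergence_fraction"] > 0.99

    def test_empty_candidates_rejected(self, uniform_camera):
        import pandas as pd

        cfg = SimulationConfig(n_frames=2, rng_seed=0)
        em = make_emitters("constant-grid", uniform_camera.shape,
                           cfg.with_(grid_margin_px=32, grid_spacing_px=64), seed=0)
        movie = simulate_movie(em, uniform_camera, cfg, seed=0)
        with pytest.raises(ValueError, match="empty"):
            batch_fit(movie, uniform_camera, pd.DataFrame(columns=["frame", "row", "col"]),
                      "mle")

    def test_edge_candidates_skipped(self, uniform_camera):
        import pandas as pd

        cfg = SimulationConfig(n_frames=2, rng_seed=0)
        em = make_emitters("constant-grid", uniform_camera.shape,
                           cfg.with_(grid_margin_px=32, grid_spacing_px=64), seed=0)
        movie = simulate_movie(em, uniform_camera, cfg, seed=0)
        cands = pd.DataFrame(
            {"frame": [0, 0], "row": [2, 32], "col": [2, 32]}
        )
        table = batch_fit(movie, uniform_camera, cands, "mle")
        assert table.attrs["n_edge_skipped"] == 1
        assert len(table) == 1


class TestSignificance:
    def test_matches_closed_form(self):
        # signal 60 e- over a 100 e- background: significance 6
        sigma = 1.5
        area = 2 * np.pi * sigma**2
        height = 60.0 / area
        background = 100.0 / area
        assert significance_from_fit(height, background, sigma) == pytest.approx(6.0)
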