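"""Cramér–Rao lower bound under the sCMOS + RQE noise model.

For an emitter whose expected pixel response is

    mu_i(theta) = rqe_i * f(theta) + var_i

(with ``f`` the Gaussian PSF model in e-, ``var_i`` the read-noise
variance in e-^2 acting as the Poisson-absorbed read-noise term), the
Fisher information of the Poisson likelihood reduces to

    F_mn = sum_i rqe_i^2 / (rqe_i f(theta) + var_i) * df/dtheta_n * df/dtheta_m

and the minimum attainable variance of any unbiased estimator of
``theta_m`` is the (m, m) element of the inverse of F.  Because the RQE
and read noise vary pixel to pixel, the bound depends on where the
emitter sits on the sensor; figure-style outputs therefore average the
bound over many emitter positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationMap
from .fit import roi_half_width
from .psf import PARAM_NAMES_4, PARAM_NAMES_5, psf_values_and_jacobian, roi_grid

__all__ = ["CRLBResult", "fisher_matrix", "crlb_bounds", "crlb_at_positions"]


@dataclass
class CRLBResult:
    """Lower-bound standard deviations and the Fisher matrix behind them.

    ``bounds`` maps parameter name -> std lower bound: positions in
    pixels (``x0_nm``/``y0_nm`` added when a pixel size is known), height
    and background in e-.
    """

    bounds: dict[str, float]
    fisher: np.ndarray
    theta: np.ndarray
    pixel_size_nm: float | None = None


def fisher_matrix(
    theta: np.ndarray,
    calib_roi: dict[str, np.ndarray],
    sigma: float | None = None,
    psf_model: str = "integrated",
) -> np.ndarray:
    """Fisher information matrix over an ROI.

    ``theta`` is ``(h, x0, y0, bg)`` (ROI-local coordinates) or the
    5-parameter variable-width set with sigma appended.  ``calib_roi``
    needs ``rqe``, ``gain`` and ``variance`` (ADU^2; converted to e-^2
    internally) on the ROI grid.
    """
    theta = np.asarray(theta, dtype=float)
    rqe = np.asarray(calib_roi["rqe"], dtype=float).ravel()
    g = np.asarray(calib_roi["gain"], dtype=float).ravel()
    var_e2 = np.asarray(calib_roi["variance"], dtype=float).ravel() / g**2
    side = int(round(np.sqrt(rqe.size)))
    xg, yg = roi_grid((side, side))
    f, jac = psf_values_and_jacobian(theta, xg, yg, sigma=sigma, model=psf_model)
    denom = rqe * f + var_e2
    if np.any(denom <= 0):
        raise ValueError(
            "mu_i <= 0 on the ROI: the model needs f > 0 or read noise > 0 everywhere"
        )
    weight = rqe**2 / denom
    fisher = np.einsum("i,pi,qi->pq", weight, jac, jac)
    return 0.5 * (fisher + fisher.T)  # exact symmetry despite summation order


def crlb_bounds(
    theta: np.ndarray,
    calib_roi: dict[str, np.ndarray],
    sigma: float | None = None,
    psf_model: str = "integrated",
    pixel_size_nm: float | None = None,
) -> CRLBResult:
    """Per-parameter standard-deviation lower bounds (inverse-Fisher diagonal)."""
    theta = np.asarray(theta, dtype=float)
    fisher = fisher_matrix(theta, calib_roi, sigma=sigma, psf_model=psf_model)
    try:
        cov = np.linalg.inv(fisher)
    except np.linalg.LinAlgError as err:
        diag = np.diag(fisher)
        names = PARAM_NAMES_5 if theta.size == 5 else PARAM_NAMES_4
        bad = names[int(np.argmin(diag))]
        raise ValueError(
            f"Fisher matrix is singular (least-informative parameter: {bad})"
        ) from err
    variances = np.diag(cov)
    if np.any(variances < 0):
        raise ValueError("Fisher inverse has negative diagonal; matrix is not PSD")
    stds = np.sqrt(variances)
    names = PARAM_NAMES_5 if theta.size == 5 else PARAM_NAMES_4
    bounds = dict(zip(names, stds.tolist()))
    if pixel_size_nm is not None:
        bounds["x0_nm"] = bounds["x0"] * pixel_size_nm
        bounds["y0_nm"] = bounds["y0"] * pixel_size_nm
    return CRLBResult(bounds=bounds, fisher=fisher, theta=theta, pixel_size_nm=pixel_size_nm)


def crlb_at_positions(
    calib: CalibrationMap,
    positions: np.ndarray,
    photons: float,
    background: float,
    sigma: float = 1.5,
    psf_model: str = "integrated",
) -> dict[str, float]:
    """Average (and median) CRLB over many emitter positions on the sensor.

    For each position the bound is computed on the same window the fitter
    uses (square, half-width ceil(3 sigma)), then summarized across
    positions — the protocol used for figure-style precision limits.
    Positions whose window leaves the sensor are skipped.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    half = roi_half_width(sigma)
    height = photons / (2.0 * np.pi * sigma**2)
    h, w = calib.shape
    per_pos: list[dict[str, float]] = []
    for x, y in positions:
        r, c = int(round(y)), int(round(x))
        if not (half <= r < h - half and half <= c < w - half):
            continue
        roi = calib.crop(r - half, r + half + 1, c - half, c + half + 1)
        theta = np.array([height, x - (c - half), y - (r - half), background])
        res = crlb_bounds(
            theta,
            {"rqe": roi.rqe, "gain": roi.gain, "variance": roi.variance},
            sigma=sigma,
            psf_model=psf_model,
            pixel_size_nm=calib.pixel_size_nm,
        )
        per_pos.append(res.bounds)
    if not per_pos:
        raise ValueError("no position left a full fit window inside the sensor")
    keys = per_pos[0].keys()
    out: dict[str, float] = {}
    for k in keys:
        vals = np.array([b[k] for b in per_pos])
        out[f"mean_{k}"] = float(vals.mean())
        out[f"median_{k}"] = float(np.median(vals))
    out["n_positions"] = len(per_pos)
    return out
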