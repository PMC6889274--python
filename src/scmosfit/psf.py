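"""2-D Gaussian PSF models and their analytic derivatives.

Two pixelization conventions are supported and shared by the simulator,
the fitters and the CRLB calculation:

* ``"integrated"`` (default): the Gaussian is integrated over each pixel
  (error-function model) — the physically correct photon count collected
  by a square pixel;
* ``"sampled"``: the Gaussian is sampled at the pixel center,
  ``f = h * exp(-((x-x0)^2+(y-y0)^2) / (2 sigma^2)) + bg``.

In both conventions the parameter vector is ``theta = (h, x0, y0, bg)``
(optionally ``(h, x0, y0, bg, sigma)``) where ``h`` is the *peak height*
in photo-electrons, positions are in pixels with pixel ``i`` centered at
integer coordinate ``i``, and ``bg`` is a uniform background per pixel.
The total photon count of an emitter is ``h * 2 pi sigma^2`` under either
convention, so heights are directly comparable between them.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["psf_values", "psf_values_and_jacobian", "roi_grid", "total_photons"]

_SQRT2 = np.sqrt(2.0)
_SQRT2PI = np.sqrt(2.0 * np.pi)

PARAM_NAMES_4 = ("height", "x0", "y0", "background")
PARAM_NAMES_5 = PARAM_NAMES_4 + ("sigma",)


def total_photons(height: np.ndarray | float, sigma: float) -> np.ndarray | float:
    """Integrated photon count of a Gaussian spot of the given peak height."""
    return height * 2.0 * np.pi * sigma**2


def roi_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Flattened (x, y) pixel-center coordinates of an ROI, C-order."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return xx.ravel().astype(float), yy.ravel().astype(float)


def _pixel_edges(c: np.ndarray, c0: np.ndarray, sigma: np.ndarray):
    """erf arguments at the +/- half-pixel edges; shapes broadcast."""
    up = (c - c0 + 0.5) / (_SQRT2 * sigma)
    um = (c - c0 - 0.5) / (_SQRT2 * sigma)
    return up, um


def _eint(c, c0, sigma):
    """Unit-mass 1-D pixel integral E(c) = 0.5 [erf(u+) - erf(u-)]."""
    up, um = _pixel_edges(c, c0, sigma)
    return 0.5 * (erf(up) - erf(um))


def psf_values(
    theta: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    sigma: float | None = None,
    model: str = "integrated",
) -> np.ndarray:
    """Evaluate the PSF model on flattened pixel coordinates.

    Parameters
    ----------
    theta : ndarray, shape (..., 4) or (..., 5)
        (h, x0, y0, bg) with sigma appended for the variable-width model;
        when 4 parameters are given ``sigma`` must be passed.
    x, y : ndarray, shape (npix,)
        Pixel-center coordinates (see :func:`roi_grid`).

    Returns
    -------
    ndarray, shape (..., npix)
    """
    theta = np.asarray(theta, dtype=float)
    n_par = theta.shape[-1]
    h = theta[..., 0:1]
    x0 = theta[..., 1:2]
    y0 = theta[..., 2:3]
    bg = theta[..., 3:4]
    if n_par == 5:
        sig = theta[..., 4:5]
    elif sigma is not None:
        sig = np.asarray(float(sigma))
    else:
        raise ValueError("sigma must be given for the 4-parameter model")
    if model == "integrated":
        amp = h * 2.0 * np.pi * sig**2
        return amp * _eint(x, x0, sig) * _eint(y, y0, sig) + bg
    if model == "sampled":
        r2 = (x - x0) ** 2 + (y - y0) ** 2
        return h * np.exp(-r2 / (2.0 * sig**2)) + bg
    raise ValueError(f"unknown PSF model {model!r}")


def psf_values_and_jacobian(
    theta: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    sigma: float | None = None,
    model: str = "integrated",
) -> tuple[np.ndarray, np.ndarray]:
    """Model values and the Jacobian d f / d theta.

    Returns ``(values, jac)`` with shapes ``(..., npix)`` and
    ``(..., n_par, npix)``; ``n_par`` follows ``theta``.
    """
    theta = np.asarray(theta, dtype=float)
    n_par = theta.shape[-1]
    h = theta[..., 0:1]
    x0 = theta[..., 1:2]
    y0 = theta[..., 2:3]
    if n_par == 5:
        sig = theta[..., 4:5]
    elif sigma is not None:
        sig = np.asarray(float(sigma))
    else:
        raise ValueError("sigma must be given for the 4-parameter model")

    if model == "sampled":
        gx = np.exp(-((x - x0) ** 2) / (2.0 * sig**2))
        gy = np.exp(-((y - y0) ** 2) / (2.0 * sig**2))
        g = gx * gy
        values = h * g + theta[..., 3:4]
        d_h = g
        d_x0 = h * g * (x - x0) / sig**2
        d_y0 = h * g * (y - y0) / sig**2
        d_bg = np.ones_like(values)
        parts = [d_h, d_x0, d_y0, d_bg]
        if n_par == 5:
            parts.append(h * g * ((x - x0) ** 2 + (y - y0) ** 2) / sig**3)
        jac = np.stack(np.broadcast_arrays(*parts), axis=-2)
        return values, jac

    if model != "integrated":
        raise ValueError(f"unknown PSF model {model!r}")

    amp = h * 2.0 * np.pi * sig**2
    uxp, uxm = _pixel_edges(x, x0, sig)
    uyp, uym = _pixel_edges(y, y0, sig)
    ex = 0.5 * (erf(uxp) - erf(uxm))
    ey = 0.5 * (erf(uyp) - erf(uym))
    gxp, gxm = np.exp(-(uxp**2)), np.exp(-(uxm**2))
    gyp, gym = np.exp(-(uyp**2)), np.exp(-(uym**2))
    values = amp * ex * ey + theta[..., 3:4]
    # dE/dc0 = -(exp(-u+^2) - exp(-u-^2)) / (sqrt(2 pi) sigma)
    dex_dx0 = -(gxp - gxm) / (_SQRT2PI * sig)
    dey_dy0 = -(gyp - gym) / (_SQRT2PI * sig)
    d_h = 2.0 * np.pi * sig**2 * ex * ey
    d_x0 = amp * dex_dx0 * ey
    d_y0 = amp * ex * dey_dy0
    d_bg = np.ones_like(values)
    parts = [d_h, d_x0, d_y0, d_bg]
    if n_par == 5:
        # dE/dsigma = -(exp(-u+^2) u+ - exp(-u-^2) u-) / (sqrt(pi) sigma)
        dex_ds = -(gxp * uxp - gxm * uxm) / (np.sqrt(np.pi) * sig)
        dey_ds = -(gyp * uyp - gym * uym) / (np.sqrt(np.pi) * sig)
        d_sig = h * 2.0 * np.pi * (
            2.0 * sig * ex * ey + sig**2 * (dex_ds * ey + ex * dey_ds)
        )
        parts.append(d_sig)
    jac = np.stack(np.broadcast_arrays(*parts), axis=-2)
    return values, jac
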