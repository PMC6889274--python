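"""Photon-transfer calibration of an sCMOS camera.

Estimates per-pixel offset, read-noise variance, gain and relative quantum
efficiency (RQE) from a dark movie plus a series of uniformly illuminated
movies, following the standard photon-transfer approach:

* offset ``o_i`` and read-noise variance ``var_i`` are the temporal mean
  and (population) variance of each pixel in the dark;
* gain ``g_i`` is the slope of a per-pixel least-squares line through the
  dark-corrected (mean, variance) points of the illuminated levels, with a
  point pinned at the origin — for a Poisson photon flux the variance in
  ADU^2 is ``g_i`` times the mean in ADU;
* RQE ``rqe_i`` is the converted (e-) mean image at the highest level
  divided by its own 10x10 uniform-filtered version, so it measures the
  *local relative* photon sensitivity of each pixel and is ~1 by
  construction.

Lamp intensity fluctuations add a common-mode variance term to every
pixel; it is estimated from the variance of the per-frame spatial mean and
subtracted before the gain fit.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import uniform_filter

from .calibration import CalibrationMap
from .movie import CameraMovie, IlluminationSeries

__all__ = [
    "compute_offset_variance",
    "lamp_corrected_stats",
    "fit_gain",
    "compute_rqe",
    "calibrate_camera",
]


def compute_offset_variance(dark: CameraMovie) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel temporal mean (offset) and population variance of a dark movie.

    The variance uses divisor M (mean of squares minus square of mean),
    not the M-1 sample form.
    """
    dark.require_statistics()
    frames = np.asarray(dark.frames, dtype=float)
    offset = frames.mean(axis=0)
    variance = (frames**2).mean(axis=0) - offset**2
    # mean-of-squares can go epsilon-negative in floating point
    np.clip(variance, 0.0, None, out=variance)
    return offset, variance


def lamp_corrected_stats(
    level: CameraMovie,
    dark_offset: np.ndarray,
    dark_variance: np.ndarray,
    clip_negative: bool = True,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Dark- and lamp-corrected temporal statistics of one illuminated movie.

    Returns ``(corrected_mean, corrected_variance, n_clipped)`` where
    ``corrected_mean = D_i - o_i`` and ``corrected_variance = V_i - var_i -
    lamp`` with ``lamp`` the variance of the per-frame spatial-average
    intensity (common-mode lamp flicker seen identically by every pixel).
    Negative corrected variances are clipped at 0; ``n_clipped`` counts them.
    """
    level.require_statistics()
    if level.frame_shape != dark_offset.shape:
        raise ValueError(
            f"level frame shape {level.frame_shape} != calibration shape {dark_offset.shape}"
        )
    frames = np.asarray(level.frames, dtype=float)
    mean = frames.mean(axis=0)
    var = (frames**2).mean(axis=0) - mean**2
    frame_means = frames.mean(axis=(1, 2))
    lamp_var = float(frame_means.var())  # population variance, divisor M
    corr_mean = mean - dark_offset
    corr_var = var - lamp_var - dark_variance
    n_clipped = 0
    if clip_negative:
        n_clipped = int(np.count_nonzero(corr_var < 0))
        np.clip(corr_var, 0.0, None, out=corr_var)
    return corr_mean, corr_var, n_clipped


def fit_gain(
    corrected_stats: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean-variance line fit; the slope is the gain in ADU/e-.

    Fits ``variance = g * mean + b`` by equally weighted least squares over
    the K corrected (mean, variance) points plus a point pinned at the
    origin.  Returns ``(gain, intercept)`` maps.  Pixels with a degenerate
    abscissa (all corrected means equal) get NaN gain and a warning.
    """
    if len(corrected_stats) == 0:
        raise ValueError("need at least one illumination level to fit gain")
    means = np.stack([m for m, _ in corrected_stats] + [np.zeros_like(corrected_stats[0][0])])
    varis = np.stack([v for _, v in corrected_stats] + [np.zeros_like(corrected_stats[0][1])])
    n = means.shape[0]
    sx = means.sum(axis=0)
    sy = varis.sum(axis=0)
    sxx = (means**2).sum(axis=0)
    sxy = (means * varis).sum(axis=0)
    denom = n * sxx - sx**2
    degenerate = denom <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = (n * sxy - sx * sy) / denom
        intercept = (sy - gain * sx) / n
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} pixels have a degenerate mean-variance "
            "abscissa; their gain is NaN",
            stacklevel=2,
        )
        gain[degenerate] = np.nan
        intercept[degenerate] = np.nan
    return gain, intercept


def compute_rqe(
    highest_level: CameraMovie,
    offset: np.ndarray,
    gain: np.ndarray,
    kernel_size: int = 10,
    boundary_mode: str = "reflect",
) -> np.ndarray:
    """Relative quantum efficiency from the brightest calibration movie.

    The temporal mean is converted to photo-electrons, ``im_i = (mean - o_i)
    / g_i``; a smoothed version ``sm_i`` is obtained by convolution with the
    normalized ``kernel_size x kernel_size`` uniform kernel; ``rqe_i = im_i
    / sm_i``.  The local normalization removes long-range illumination
    non-uniformity, so the result is a *relative* efficiency with local
    mean ~1.
    """
    if np.any(gain <= 0):
        raise ValueError("gain must be positive everywhere to convert ADU to e-")
    highest_level.require_statistics()
    mean = np.asarray(highest_level.frames, dtype=float).mean(axis=0)
    im = (mean - offset) / gain
    sm = uniform_filter(im, size=kernel_size, mode=boundary_mode)
    if np.any(sm <= 0):
        raise ValueError(
            "smoothed converted image has non-positive values; illumination "
            "is too low or the offset is miscalibrated"
        )
    return im / sm


def calibrate_camera(
    series: IlluminationSeries,
    kernel_size: int = 10,
    boundary_mode: str = "reflect",
) -> CalibrationMap:
    """Full calibration: offset, read-noise variance, gain and RQE maps.

    Composes :func:`compute_offset_variance`, :func:`lamp_corrected_stats`
    per level, :func:`fit_gain` and :func:`compute_rqe` (on the last,
    brightest level).  The returned map's :meth:`~scmosfit.calibration.CalibrationMap.summary`
    carries the pixel-variability statistics (std of gain and RQE, their
    correlation).
    """
    series.validate()
    offset, variance = compute_offset_variance(series.dark)
    stats = []
    for level in series.levels:
        m, v, _ = lamp_corrected_stats(level, offset, variance)
        stats.append((m, v))
    gain, intercept = fit_gain(stats)
    if np.any(~np.isfinite(gain)) or np.any(gain <= 0):
        raise ValueError(
            "gain fit produced non-positive or undefined pixels; check that "
            "the illumination levels are bright enough"
        )
    rqe = compute_rqe(
        series.levels[-1], offset, gain,
        kernel_size=kernel_size, boundary_mode=boundary_mode,
    )
    return CalibrationMap(
        offset=offset,
        variance=variance,
        gain=gain,
        rqe=rqe,
        intercept=intercept,
        pixel_size_nm=series.dark.pixel_size_nm,
    )
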