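"""Evaluation surfaces: rendered images, count-RQE correlation, accuracy.

``render`` draws each localization as a Gaussian of unit height and
sigma 1 pixel — the standard quick-look SMLM rendering, in which a pixel
value of N means roughly N localizations in or very near the pixel.

``counts_vs_rqe`` quantifies the identification artifact: it counts
localizations by the pixel they are centered on and correlates the
per-pixel counts with the smoothed RQE map.  On a striped sensor,
uncorrected analysis concentrates localizations on high-RQE pixels
(significantly positive Pearson correlation, several-fold top/bottom
quintile count ratio); RQE-corrected analysis removes the correlation.

``precision_bias`` scores fitted localizations against ground truth:
precision is the per-emitter standard deviation of the fitted position
over frames; bias is the root mean square of the per-emitter mean
position error, corrected for the sampling noise of that mean
(``bias^2 = max(0, RMS^2 - precision^2 / K)`` with K fits per emitter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .calibration import CalibrationMap
from .identify import smooth_map

__all__ = ["AccuracyReport", "render", "counts_vs_rqe", "precision_bias"]


def render(
    localizations: pd.DataFrame,
    shape: tuple[int, int],
    sigma: float = 1.0,
) -> np.ndarray:
    """Render localizations as unit-height Gaussians of the given sigma.

    Uses ``x_px`` / ``y_px`` columns; out-of-bounds localizations are
    dropped.
    """
    h, w = shape
    image = np.zeros((h, w))
    if len(localizations) == 0:
        return image
    xs = localizations["x_px"].to_numpy(float)
    ys = localizations["y_px"].to_numpy(float)
    ok = (xs > -0.5) & (xs < w - 0.5) & (ys > -0.5) & (ys < h - 0.5)
    half = int(np.ceil(5.0 * sigma))
    d = np.arange(-half, half + 1)
    for x, y in zip(xs[ok], ys[ok]):
        cx, cy = int(round(x)), int(round(y))
        x_lo, x_hi = max(0, cx - half), min(w, cx + half + 1)
        y_lo, y_hi = max(0, cy - half), min(h, cy + half + 1)
        gx = np.exp(-((np.arange(x_lo, x_hi) - x) ** 2) / (2 * sigma**2))
        gy = np.exp(-((np.arange(y_lo, y_hi) - y) ** 2) / (2 * sigma**2))
        image[y_lo:y_hi, x_lo:x_hi] += gy[:, None] * gx[None, :]
    return image


def counts_vs_rqe(
    localizations: pd.DataFrame,
    calib: CalibrationMap,
    psf_sigma_px: float,
    quantile: float = 0.2,
    interior_margin: int | None = None,
) -> dict:
    """Per-pixel localization counts against smoothed RQE.

    Returns the count map, (smoothed RQE, count) scatter pairs over the
    analyzed pixels, their Pearson r and p-value, and the ratio of total
    counts on the top versus bottom ``quantile`` of pixels by smoothed
    RQE.  ``interior_margin`` restricts the analysis to pixels at least
    that far from the sensor edge (where detection has full support);
    default: the identification window half-width, ceil(5 sigma).
    """
    h, w = calib.shape
    counts = np.zeros((h, w))
    if {"x_px", "y_px"}.issubset(localizations.columns):
        cols = np.rint(localizations["x_px"].to_numpy(float)).astype(int)
        rows = np.rint(localizations["y_px"].to_numpy(float)).astype(int)
    else:
        rows = localizations["row"].to_numpy(int)
        cols = localizations["col"].to_numpy(int)
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    np.add.at(counts, (rows[ok], cols[ok]), 1.0)

    smoothed = smooth_map(calib.rqe, psf_sigma_px)
    margin = int(np.ceil(5.0 * psf_sigma_px)) if interior_margin is None else interior_margin
    sl = (slice(margin, h - margin), slice(margin, w - margin)) if margin else (slice(None), slice(None))
    c = counts[sl].ravel()
    r = smoothed[sl].ravel()
    pear = pearsonr(r, c)
    lo_cut = np.quantile(r, quantile)
    hi_cut = np.quantile(r, 1.0 - quantile)
    n_top = c[r >= hi_cut].sum()
    n_bot = c[r <= lo_cut].sum()
    return {
        "count_map": counts,
        "smoothed_rqe": r,
        "counts": c,
        "pearson_r": float(pear.statistic),
        "pearson_p": float(pear.pvalue),
        "top_quintile_counts": float(n_top),
        "bottom_quintile_counts": float(n_bot),
        "quintile_ratio": float(n_top / n_bot) if n_bot > 0 else np.inf,
    }


@dataclass
class AccuracyReport:
    """Precision and precision-corrected bias of a localization table."""

    precision_x: float
    precision_y: float
    bias_x: float
    bias_y: float
    bias: float
    n_emitters: int
    n_excluded: int
    mean_frames_per_emitter: float
    units: str = "px"
    raw_rms_x: float = float("nan")
    raw_rms_y: float = float("nan")

    @property
    def precision(self) -> float:
        """Mean of the per-axis precisions."""
        return 0.5 * (self.precision_x + self.precision_y)


def precision_bias(
    localizations: pd.DataFrame,
    truth_positions: np.ndarray,
    pixel_size_nm: float | None = None,
    correct_for_precision: bool = True,
) -> AccuracyReport:
    """Score fits against ground truth, per emitter and per axis.

    ``localizations`` needs ``emitter``, ``x_px``, ``y_px`` columns (one
    row per fitted frame); ``truth_positions`` is (E, 2) as (x, y) in
    pixels, indexed by the ``emitter`` ids.  Emitters with fewer than two
    fitted frames are excluded (counted).  When a pixel size is given the
    report is in nm, else in pixels.
    """
    truth_positions = np.atleast_2d(np.asarray(truth_positions, dtype=float))
    grouped = localizations.groupby("emitter")
    dev_x, dev_y, prec_x, prec_y, k_frames = [], [], [], [], []
    n_excluded = 0
    for e_id, grp in grouped:
        if len(grp) < 2:
            n_excluded += 1
            continue
        x = grp["x_px"].to_numpy(float)
        y = grp["y_px"].to_numpy(float)
        tx, ty = truth_positions[int(e_id)]
        dev_x.append(x.mean() - tx)
        dev_y.append(y.mean() - ty)
        prec_x.append(x.std(ddof=1))
        prec_y.append(y.std(ddof=1))
        k_frames.append(len(grp))
    if not dev_x:
        raise ValueError("no emitter has at least two fitted frames")
    dev_x, dev_y = np.array(dev_x), np.array(dev_y)
    prec_x, prec_y = np.array(prec_x), np.array(prec_y)
    k = np.array(k_frames, dtype=float)

    def _bias(dev, prec):
        raw = float(np.mean(dev**2))
        corr = float(np.mean(prec**2 / k)) if correct_for_precision else 0.0
        return np.sqrt(max(0.0, raw - corr)), np.sqrt(raw)

    bx, rms_x = _bias(dev_x, prec_x)
    by, rms_y = _bias(dev_y, prec_y)
    scale = pixel_size_nm if pixel_size_nm is not None else 1.0
    return AccuracyReport(
        precision_x=float(prec_x.mean()) * scale,
        precision_y=float(prec_y.mean()) * scale,
        bias_x=bx * scale,
        bias_y=by * scale,
        bias=float(np.sqrt(bx**2 + by**2)) * scale,
        n_emitters=len(dev_x),
        n_excluded=n_excluded,
        mean_frames_per_emitter=float(k.mean()),
        units="nm" if pixel_size_nm is not None else "px",
        raw_rms_x=rms_x * scale,
        raw_rms_y=rms_y * scale,
    )
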