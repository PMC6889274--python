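"""Per-pixel camera model container.

Every pixel *i* of an sCMOS sensor has its own amplifier, hence its own
offset ``o_i`` (ADU), read-noise variance ``var_i`` (ADU^2), gain ``g_i``
(ADU per photo-electron) and relative quantum efficiency ``rqe_i``
(dimensionless, ~1, normalized to the local 10x10 neighborhood mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CalibrationMap:
    """Per-pixel offset / read-noise variance / gain / RQE maps.

    All arrays share one (H, W) shape.  ``variance`` is in ADU^2 as
    measured from dark frames; routines that need it in photo-electron
    units use :meth:`variance_e2`.  ``intercept`` is the intercept of the
    per-pixel mean-variance line fit and is diagnostic only.
    """

    offset: np.ndarray
    variance: np.ndarray
    gain: np.ndarray
    rqe: np.ndarray
    intercept: np.ndarray | None = None
    pixel_size_nm: float | None = None

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        self.gain = np.asarray(self.gain, dtype=float)
        self.rqe = np.asarray(self.rqe, dtype=float)
        shape = self.offset.shape
        for name in ("variance", "gain", "rqe"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != offset shape {shape}")
        if self.intercept is not None:
            self.intercept = np.asarray(self.intercept, dtype=float)
            if self.intercept.shape != shape:
                raise ValueError("intercept shape mismatch")
        if np.any(self.gain <= 0):
            raise ValueError("gain must be positive everywhere")
        if np.any(self.rqe <= 0):
            raise ValueError("rqe must be positive everywhere")
        if np.any(self.variance < 0):
            raise ValueError("read-noise variance must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.offset.shape

    @property
    def mean_gain(self) -> float:
        """Arithmetic mean of the per-pixel gains, <g_i> (ADU/e-)."""
        return float(self.gain.mean())

    def variance_e2(self) -> np.ndarray:
        """Read-noise variance converted from ADU^2 to e-^2 (var_i / g_i^2)."""
        return self.variance / self.gain**2

    def flat_field(self) -> np.ndarray:
        """Flat-field correction factor flat_i = (g_i * rqe_i) / <g_i>."""
        return self.gain * self.rqe / self.mean_gain

    def summary(self) -> dict[str, float]:
        """Scalar summary statistics of the pixel-to-pixel variability."""
        g = self.gain.ravel()
        r = self.rqe.ravel()
        corr = float(np.corrcoef(g, r)[0, 1]) if g.size > 1 else float("nan")
        return {
            "mean_gain": self.mean_gain,
            "std_gain": float(g.std()),
            "std_rqe": float(r.std()),
            "mean_offset": float(self.offset.mean()),
            "mean_variance": float(self.variance.mean()),
            "gain_rqe_correlation": corr,
        }

    def crop(self, row0: int, row1: int, col0: int, col1: int) -> "CalibrationMap":
        """Return the calibration of a rectangular sub-region of the sensor."""
        sl = (slice(row0, row1), slice(col0, col1))
        return CalibrationMap(
            offset=self.offset[sl],
            variance=self.variance[sl],
            gain=self.gain[sl],
            rqe=self.rqe[sl],
            intercept=None if self.intercept is None else self.intercept[sl],
            pixel_size_nm=self.pixel_size_nm,
        )

    @classmethod
    def uniform(
        cls,
        shape: tuple[int, int],
        offset: float = 100.0,
        variance: float = 0.0,
        gain: float = 1.0,
        rqe: float = 1.0,
        pixel_size_nm: float | None = None,
    ) -> "CalibrationMap":
        """An idealized camera with identical pixels (useful as a null model)."""
        full = lambda v: np.full(shape, float(v))
        return cls(
            offset=full(offset),
            variance=full(variance),
            gain=full(gain),
            rqe=full(rqe),
            pixel_size_nm=pixel_size_nm,
        )
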