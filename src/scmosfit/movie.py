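"""Camera-frame containers.

An sCMOS acquisition is a stack of frames of raw ADU counts.  Per-pixel
statistics over time (mean, variance) are the raw material of the
photon-transfer calibration, so the containers here enforce the minimal
invariants those statistics need: finite values and at least two frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CameraMovie:
    """A stack of camera frames in raw ADU.

    Parameters
    ----------
    frames : ndarray, shape (M, H, W)
        ADU counts, frame index first.
    pixel_size_nm : float, optional
        Physical back-projected pixel size; metadata only.
    """

    frames: np.ndarray
    pixel_size_nm: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (M, H, W), got shape {self.frames.shape}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite ADU values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def require_statistics(self) -> None:
        """Raise unless temporal statistics are well defined (M >= 2)."""
        if self.n_frames < 2:
            raise ValueError(
                f"need at least 2 frames for temporal statistics, got {self.n_frames}"
            )


@dataclass
class IlluminationSeries:
    """A dark movie plus K illuminated movies at increasing intensity.

    This is the input of the photon-transfer calibration: the dark movie
    fixes offset and read-noise variance, the illuminated levels trace out
    the per-pixel mean-variance line whose slope is the gain.
    """

    dark: CameraMovie
    levels: list[CameraMovie] = field(default_factory=list)

    def __post_init__(self) -> None:
        shape = self.dark.frame_shape
        for k, level in enumerate(self.levels):
            if level.frame_shape != shape:
                raise ValueError(
                    f"level {k} frame shape {level.frame_shape} != dark {shape}"
                )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def validate(self) -> None:
        """Check the series is usable for calibration."""
        if self.n_levels < 1:
            raise ValueError("calibration needs at least one illuminated level")
        self.dark.require_statistics()
        dark_mean = float(self.dark.frames.mean())
        for k, level in enumerate(self.levels):
            level.require_statistics()
            if float(level.frames.mean()) <= dark_mean:
                raise ValueError(
                    f"level {k} mean ADU does not exceed the dark mean; "
                    "levels must be ordered dark-first and actually illuminated"
                )
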