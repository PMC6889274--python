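"""Pixel-faithful forward simulation of SMLM movies on an sCMOS camera.

The forward model mirrors the physical signal chain: the photon
expectation of each pixel (PSF-rendered emitters plus uniform background)
is multiplied by the pixel's relative quantum efficiency, a Poisson
photo-electron count is drawn, multiplied by the pixel gain, Gaussian
read noise of the pixel's measured standard deviation is added, and
finally the pixel offset:

    ADU_i = g_i * Poisson(rqe_i * mu_i) + Normal(0, sqrt(var_i)) + o_i

The module also synthesizes camera calibrations that emulate measured
sCMOS sensors — ~4% pixel-to-pixel standard deviation in both gain and
RQE, the two anti-correlated, with a vertically striped RQE pattern —
and illumination series for exercising the calibration pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter

from .calibration import CalibrationMap
from .movie import CameraMovie, IlluminationSeries
from .psf import psf_values, roi_grid

__all__ = [
    "SimulationConfig",
    "EmitterSet",
    "synth_calibration",
    "make_emitters",
    "render_expectation",
    "camera_forward",
    "simulate_movie",
    "simulate_illumination_series",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimulationConfig:
    """Study conditions of a simulated SMLM acquisition.

    Defaults are the reference conditions used throughout: emitters at a
    constant 250 photons/frame when on, a uniform background of 20
    photons/pixel, a Gaussian PSF of sigma 1.5 pixels at 100 nm pixel
    size, and (in blinking mode) a mean off-time of 2 frames.
    """

    n_frames: int = 1000
    photons_per_frame: float = 250.0
    background_photons: float = 20.0
    psf_sigma_px: float = 1.5
    pixel_size_nm: float = 100.0
    density_per_um2: float = 0.15
    off_rate_frames: float = 2.0
    on_frames: float = 1.0
    grid_spacing_px: int = 20
    grid_margin_px: int = 10
    grid_subpixel_jitter: bool = True
    psf_model: str = "integrated"
    quantize_adu: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_frames", "photons_per_frame", "psf_sigma_px", "pixel_size_nm",
            "density_per_um2", "off_rate_frames", "on_frames", "grid_spacing_px",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.background_photons < 0:
            raise ValueError("background_photons must be non-negative")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class EmitterSet:
    """Ground-truth emitters: positions, intensities, per-frame on/off states.

    ``positions`` is (N, 2) as (x, y) in pixel units (pixel centers at
    integer coordinates); ``on_state`` is (N, n_frames) boolean;
    ``intensity`` is photons/frame when on, scalar or per-emitter.
    """

    positions: np.ndarray
    intensity: np.ndarray
    on_state: np.ndarray
    frame_shape: tuple[int, int]
    layout: str = "uniform-random"

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.intensity = np.broadcast_to(
            np.asarray(self.intensity, dtype=float), (self.n_emitters,)
        ).copy()
        self.on_state = np.atleast_2d(np.asarray(self.on_state, dtype=bool))
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        h, w = self.frame_shape
        x, y = self.positions[:, 0], self.positions[:, 1]
        if np.any((x < -0.5) | (x > w - 0.5) | (y < -0.5) | (y > h - 0.5)):
            raise ValueError("emitter positions must lie inside the frame")

    @property
    def n_emitters(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.on_state.shape[1]

    def always_on(self) -> bool:
        return bool(self.on_state.all())


def synth_calibration(
    shape: tuple[int, int],
    gain_mean: float = 2.0,
    gain_std_frac: float = 0.04,
    rqe_std_frac: float = 0.04,
    gain_rqe_corr: float = -0.9,
    stripe_sigma_px: float = 2.0,
    stripe_var_frac: float = 0.7,
    readnoise_var_range: tuple[float, float] = (4.0, 36.0),
    offset_mean: float = 100.0,
    offset_std: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> CalibrationMap:
    """Synthesize a calibration emulating a measured sCMOS sensor.

    The RQE field is the sum of a vertically striped component (a common
    column profile: white noise smoothed along x with a Gaussian of
    ``stripe_sigma_px``, carrying ``stripe_var_frac`` of the variance) and
    independent pixel noise, normalized by its own 10x10 uniform-filtered
    version so the local mean is ~1 — the same normalization the RQE
    measurement itself applies.  The gain field is built to have the
    requested correlation with the RQE fluctuations.  Read-noise variance
    (ADU^2) is drawn uniformly from ``readnoise_var_range`` per pixel.
    Deterministic given ``seed``.
    """
    if not (0.0 <= gain_std_frac < 0.2 and 0.0 <= rqe_std_frac < 0.2):
        raise ValueError("gain/rqe std fractions must be in [0, 0.2)")
    if abs(gain_rqe_corr) > 1.0:
        raise ValueError("|gain_rqe_corr| must be <= 1")
    if not 0.0 <= stripe_var_frac <= 1.0:
        raise ValueError("stripe_var_frac must be in [0, 1]")
    rng = _rng(seed)
    h, w = shape

    col_profile = gaussian_filter1d(rng.standard_normal(w), stripe_sigma_px, mode="wrap")
    col_profile -= col_profile.mean()
    sd = col_profile.std()
    if sd > 0:
        col_profile /= sd
    pixel_noise = rng.standard_normal(shape)
    z_rqe = np.sqrt(stripe_var_frac) * col_profile[None, :] + np.sqrt(
        1.0 - stripe_var_frac
    ) * pixel_noise

    if rqe_std_frac > 0:
        # the 10x10 local normalization is applied LAST (it is what the RQE
        # measurement itself does, and it keeps every 10x10 window mean ~1);
        # the fluctuation scale is adjusted so the realized std hits target
        scale = rqe_std_frac
        for _ in range(3):
            raw = 1.0 + scale * z_rqe
            rqe = raw / uniform_filter(raw, size=10, mode="reflect")
            # second pass pins every (offset) 10x10 window mean within ~1.5%
            rqe = rqe / uniform_filter(rqe, size=10, mode="reflect")
            sd = rqe.std()
            if sd <= 0:
                break
            scale *= rqe_std_frac / sd
        z = (rqe - rqe.mean()) / rqe.std()
    else:
        rqe = np.ones(shape)
        z = np.zeros(shape)

    z_indep = rng.standard_normal(shape)
    z_gain = gain_rqe_corr * z + np.sqrt(max(0.0, 1.0 - gain_rqe_corr**2)) * z_indep
    gain = gain_mean * (1.0 + gain_std_frac * z_gain)
    if np.any(gain <= 0):
        raise ValueError("generated gain has non-positive pixels; reduce gain_std_frac")

    lo, hi = readnoise_var_range
    if lo < 0 or hi < lo:
        raise ValueError("readnoise_var_range must be 0 <= lo <= hi")
    variance = rng.uniform(lo, hi, size=shape)
    offset = offset_mean + offset_std * rng.standard_normal(shape)
    return CalibrationMap(offset=offset, variance=variance, gain=gain, rqe=rqe)


def _blinking_states(
    n_emitters: int, n_frames: int, on_frames: float, off_frames: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Two-state Markov chain: geometric on/off dwell times with the given means."""
    p_off_to_on = min(1.0, 1.0 / off_frames)
    p_on_to_off = min(1.0, 1.0 / on_frames)
    p_on_stationary = on_frames / (on_frames + off_frames)
    states = np.empty((n_emitters, n_frames), dtype=bool)
    state = rng.random(n_emitters) < p_on_stationary
    u = rng.random((n_emitters, n_frames))
    for m in range(n_frames):
        states[:, m] = state
        flip_on = ~state & (u[:, m] < p_off_to_on)
        flip_off = state & (u[:, m] < p_on_to_off)
        state = (state | flip_on) & ~flip_off
    return states


def make_emitters(
    mode: str,
    frame_shape: tuple[int, int],
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> EmitterSet:
    """Generate a ground-truth emitter configuration.

    ``"blinking-uniform"``: a Poisson-distributed number of uniformly
    placed emitters at ``density_per_um2``, blinking as a two-state chain
    with mean off-time ``off_rate_frames`` and mean on-time ``on_frames``.

    ``"constant-grid"``: emitters on a square grid with
    ``grid_spacing_px`` separation (optionally jittered by a uniform
    sub-pixel offset), on in every frame.
    """
    rng = _rng(config.rng_seed if seed is None else seed)
    h, w = frame_shape
    if mode == "blinking-uniform":
        area_um2 = h * w * (config.pixel_size_nm / 1000.0) ** 2
        n = int(rng.poisson(config.density_per_um2 * area_um2))
        if n == 0:
            raise ValueError(
                "density and frame size produced zero emitters; enlarge the frame"
            )
        pos = np.column_stack(
            [rng.uniform(-0.5, w - 0.5, n), rng.uniform(-0.5, h - 0.5, n)]
        )
        on = _blinking_states(
            n, config.n_frames, config.on_frames, config.off_rate_frames, rng
        )
        layout = "uniform-random"
    elif mode == "constant-grid":
        s, m = config.grid_spacing_px, config.grid_margin_px
        xs = np.arange(m, w - m + 1, s, dtype=float)
        ys = np.arange(m, h - m + 1, s, dtype=float)
        if xs.size == 0 or ys.size == 0:
            raise ValueError("grid spacing/margin leave no emitters in the frame")
        gx, gy = np.meshgrid(xs, ys)
        pos = np.column_stack([gx.ravel(), gy.ravel()])
        if config.grid_subpixel_jitter:
            pos = pos + rng.uniform(-0.5, 0.5, pos.shape)
        on = np.ones((pos.shape[0], config.n_frames), dtype=bool)
        layout = "grid"
    else:
        raise ValueError(f"unknown emitter mode {mode!r}")
    return EmitterSet(
        positions=pos,
        intensity=config.photons_per_frame,
        on_state=on,
        frame_shape=frame_shape,
        layout=layout,
    )


def render_expectation(
    emitters: EmitterSet,
    frame_index: int,
    config: SimulationConfig,
) -> np.ndarray:
    """Photon-expectation image of one frame: ON emitters' PSFs + background.

    Each emitter contributes a 2-D Gaussian of total photons equal to its
    intensity; the PSF pixelization convention follows ``config.psf_model``.
    """
    h, w = emitters.frame_shape
    image = np.full((h, w), float(config.background_photons))
    sigma = config.psf_sigma_px
    half = int(np.ceil(5.0 * sigma))
    on = emitters.on_state[:, frame_index]
    for j in np.flatnonzero(on):
        x0, y0 = emitters.positions[j]
        height = emitters.intensity[j] / (2.0 * np.pi * sigma**2)
        cx, cy = int(round(x0)), int(round(y0))
        x_lo, x_hi = max(0, cx - half), min(w, cx + half + 1)
        y_lo, y_hi = max(0, cy - half), min(h, cy + half + 1)
        xg, yg = roi_grid((y_hi - y_lo, x_hi - x_lo))
        theta = np.array([height, x0 - x_lo, y0 - y_lo, 0.0])
        patch = psf_values(theta, xg, yg, sigma=sigma, model=config.psf_model)
        image[y_lo:y_hi, x_lo:x_hi] += patch.reshape(y_hi - y_lo, x_hi - x_lo)
    return image


def camera_forward(
    expectation: np.ndarray,
    calib: CalibrationMap,
    seed: int | np.random.Generator,
    quantize: bool = False,
) -> np.ndarray:
    """One pass through the camera: RQE -> Poisson -> gain -> read noise -> offset.

    ``expectation`` may be a single frame (H, W) or a stack (M, H, W)
    sharing one calibration.  Returns ADU, float64 (or rounded to integers
    when ``quantize``).
    """
    expectation = np.asarray(expectation, dtype=float)
    if np.any(expectation < 0):
        raise ValueError("photon expectation must be non-negative")
    if expectation.shape[-2:] != calib.shape:
        raise ValueError(
            f"expectation shape {expectation.shape[-2:]} != calibration {calib.shape}"
        )
    rng = _rng(seed)
    electrons = rng.poisson(calib.rqe * expectation).astype(float)
    adu = calib.gain * electrons
    adu += rng.normal(0.0, np.sqrt(calib.variance), size=expectation.shape)
    adu += calib.offset
    if quantize:
        np.rint(adu, out=adu)
    return adu


def simulate_movie(
    emitters: EmitterSet,
    calib: CalibrationMap,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> CameraMovie:
    """Render and camera-forward a full movie. Deterministic given seed."""
    if emitters.frame_shape != calib.shape:
        raise ValueError("emitter frame shape does not match calibration shape")
    rng = _rng(config.rng_seed if seed is None else seed)
    n = config.n_frames
    frames = np.empty((n, *calib.shape))
    if emitters.always_on():
        # constant scene: render once, draw noise frame-by-frame
        mu = render_expectation(emitters, 0, config)
        chunk = max(1, int(2e7) // mu.size)
        for lo in range(0, n, chunk):
            hi = min(n, lo + chunk)
            frames[lo:hi] = camera_forward(
                np.broadcast_to(mu, (hi - lo, *mu.shape)), calib, rng,
                quantize=config.quantize_adu,
            )
    else:
        for m in range(n):
            mu = render_expectation(emitters, m, config)
            frames[m] = camera_forward(mu, calib, rng, quantize=config.quantize_adu)
    return CameraMovie(frames=frames, pixel_size_nm=config.pixel_size_nm)


def simulate_illumination_series(
    calib: CalibrationMap,
    n_frames: int = 2000,
    max_expectation_e: float = 2000.0,
    level_fractions: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0),
    lamp_flicker_frac: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> IlluminationSeries:
    """Simulate dark + uniformly illuminated calibration movies.

    Illumination levels span the linear regime at the given fractions of
    ``max_expectation_e`` photons/pixel.  ``lamp_flicker_frac`` adds i.i.d.
    per-frame multiplicative lamp fluctuations of that fractional
    standard deviation (common to all pixels in a frame).
    """
    rng = _rng(seed)
    shape = calib.shape
    dark_adu = calib.offset + rng.normal(
        0.0, np.sqrt(calib.variance), size=(n_frames, *shape)
    )
    dark = CameraMovie(frames=dark_adu, pixel_size_nm=calib.pixel_size_nm)
    levels = []
    for frac in level_fractions:
        mu = frac * max_expectation_e
        if lamp_flicker_frac > 0:
            scale = 1.0 + lamp_flicker_frac * rng.standard_normal(n_frames)
            scale = np.clip(scale, 0.0, None)
            expectation = scale[:, None, None] * np.full((1, *shape), mu)
        else:
            expectation = np.full((n_frames, *shape), mu)
        chunk = max(1, int(2e7) // (shape[0] * shape[1]))
        frames = np.empty((n_frames, *shape))
        for lo in range(0, n_frames, chunk):
            hi = min(n_frames, lo + chunk)
            frames[lo:hi] = camera_forward(expectation[lo:hi], calib, rng)
        levels.append(CameraMovie(frames=frames, pixel_size_nm=calib.pixel_size_nm))
    return IlluminationSeries(dark=dark, levels=levels)
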