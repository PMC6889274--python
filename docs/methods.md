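# Methods

`scmosfit` analyzes single-molecule localization microscopy (SMLM) data
acquired with scientific CMOS cameras, whose per-pixel amplifiers give
every pixel its own offset, gain, read noise — and, as it turns out,
its own *relative quantum efficiency* (RQE). This note records the
models, the numerical choices, and what the synthetic experiments do and
do not demonstrate.

## Camera model

Pixel `i` is described by four numbers:

* offset `o_i` (ADU): mean dark level;
* read-noise variance `var_i` (ADU²): dark temporal variance;
* gain `g_i` (ADU/e⁻): slope of temporal variance vs. temporal mean under
  Poisson illumination (photon-transfer relation);
* RQE `rqe_i` (dimensionless, ≈1): photon sensitivity relative to the
  local 10×10-pixel neighborhood mean.

The forward model of a measured frame, given a photon expectation
`mu_i`, is

    ADU_i = g_i · Poisson(rqe_i · mu_i) + Normal(0, sqrt(var_i)) + o_i

Because the RQE is defined as a *local ratio*, long-range illumination
non-uniformity cancels out of its measurement; only relative pixel
sensitivity at sub-10-pixel scales is represented. Absolute quantum
efficiency is out of scope.

## Calibration

Offset and read-noise variance are the temporal mean and population
variance (divisor M) of a dark movie. The gain is a per-pixel,
equally-weighted least-squares line through the dark-corrected
(mean, variance) points of K illuminated movies plus a point pinned at
the origin; the fitted intercept is kept as a diagnostic only. Common-
mode lamp flicker is removed by subtracting the variance of the
per-frame spatial mean from every pixel's temporal variance before the
fit; corrected variances that come out negative (possible at low light)
are clipped at zero and counted. Mean–variance non-linearity is not
modeled; the fit is a straight line.

The RQE is the converted (e⁻) temporal mean of the brightest movie
divided by its own 10×10 uniform-filtered version
(`scipy.ndimage.uniform_filter`, `reflect` boundary by default,
configurable; the even-sized kernel uses that filter's origin
convention, so results are bit-reproducible).

Error budget: the per-pixel gain error is sampling-limited,
≈ sqrt(2/M) relative (≈2% at M = 3000 frames, ≈0.9% at 20 000), and the
RQE error is dominated by the propagated gain error — the photon
statistics of the bright movie contribute almost nothing. The
round-trip tests assert recovery at tolerances derived from this
scaling at the frame counts they actually simulate.

## Synthetic sensor

`synth_calibration` emulates a measured sCMOS sensor: RQE fluctuations
of 4% standard deviation composed of a vertically striped component (a
common column profile: white noise Gaussian-smoothed along x with
σ = 2 px, carrying 70% of the variance) plus independent pixel noise;
gain fluctuations of 4% built to be anti-correlated with the RQE
(r = −0.9); heteroscedastic read noise drawn uniformly from 4–36 ADU²
(1–3 e⁻ rms at gain 2); offsets ≈100 ± 5 ADU. The RQE field is passed
twice through the same 10×10 uniform-filter normalization that the
measurement itself applies, which pins every interior 10×10 window mean
to 1 within ~1.5%, then rescaled so the realized standard deviation hits
the target. The stripe coherence length is a modeling choice — the real
sensors' stripe spectrum is not published — and it directly sets the
strength of every artifact below: more coherent stripes survive the
PSF-scale smoothing better and give larger detection bias, enrichment,
and fitting bias.

## Identification

Frames are converted to photo-electrons either ignoring RQE,
`x = (ADU − o)/g`, or with the RQE correction `x = (ADU − o)/(g·rqe)`.
Candidates are strict local maxima of the frame smoothed with a Gaussian
of the PSF σ (matched filter), pre-filtered two smoothed-noise sigmas
above the frame median, and scored by an SNSMIL-style significance from
aperture photometry on the unsmoothed e⁻ frame: signal summed over a
disk of radius 2σ minus the local background, background per pixel from
the median of a 3σ–5σ annulus, noise = sqrt(background e⁻ in the disk).
Maxima closer than 2σ keep the higher significance (ties to the lowest
(row, col)); windows that would leave the frame are dropped. A 6σ
significance corresponds to a two-sided Gaussian tail probability of
≈2.0×10⁻⁹.

The aperture geometry is a design choice (the significance literature
does not pin it); two alternatives were implemented and compared — a
fitted-height significance `θ₁·2πσ²/sqrt(θ₄·2πσ²)` and a fitted-
background disk sum — and all three give category separations within a
few points of each other on the same sensor, because the separation is
governed by the sensor's smoothed-RQE structure, not the aperture.

One amplification mechanism is worth recording: the significance
responds to a local RQE excursion about 4× more strongly than the
smoothed RQE deviation itself, because the background reference (annulus
or fitted background) samples the *surround*, which the 10×10
normalization makes anti-correlated with the center.

## Fitting

A 2-D Gaussian PSF with θ = (height, x₀, y₀, background), σ fixed at
1.5 px by default (optionally free as a fifth parameter). Two
pixelization conventions are shared by the simulator, fitters and CRLB:
the error-function pixel-integrated Gaussian (default, physically
correct for square pixels) and the center-sampled Gaussian. Pixel `i`'s
center is at integer coordinate `i`; positions are (x, y) = (col, row).
Total photons = height·2πσ² under either convention.

Three estimators, all minimized by Levenberg–Marquardt:

* `mle` — Poisson MLE deviance `2Σ(f−x) − 2Σ x ln(f/x)` with the
  read-noise variance added to both model and data (`f = f(θ) + v`,
  `x = x_pre + v`), which absorbs Gaussian read noise into the Poisson
  likelihood; RQE assumed 1.
* `mle-rqe` — same data terms, but the *model* is multiplied per pixel
  by the RQE (`f = rqe·f(θ) + v`). This preserves the Poisson
  mean–variance relation of the data, unlike dividing the data by the
  RQE.
* `wls` — weighted least squares on flat-field-corrected data
  `x = (ADU − o)/(g·rqe)` with weights `1/(x + v)` (floored at 1 e⁻² for
  robustness at very low counts).

Unit convention: the measured read-noise variance is ADU² and is
converted to e⁻ units as `v = var/g²` before entering the shifted terms
and the CRLB denominator.

LM specifics: damping starts at 1e−3 with a ×10 / ÷10 schedule on the
Hessian diagonal (Marquardt scaling), Fisher-scoring Gauss–Newton
Hessian `2Σ (x/f²) J Jᵀ` with analytic PSF Jacobians, convergence when
an accepted step decreases the objective by less than 1e−6 relative,
at most 200 iterations, failure when the damping exceeds 1e9.
Parameters are projected onto their box after each step (height > 0,
background ≥ 0 with a bound-hit flag, center inside the window, σ ≥ 0.3
when free). Initialization is data-driven and deterministic: background
from the window border median, height from the central pixel above
background, position from the clipped-positive centroid. The fit window
is square with half-width ceil(3σ) (11 px at σ = 1.5, >99% PSF mass).
All windows advance together through a batched LM loop with per-fit
damping and accept/reject — orders of magnitude faster than per-spot
Python loops and bit-reproducible.

Data terms entering logarithms or weight denominators are floored at
1e−3 e⁻; with a 20 e⁻ background this floor is touched only in extreme
read-noise tails.

## Cramér–Rao lower bound

With model `mu_i(θ) = rqe_i·f(θ) + v_i`, the Poisson Fisher matrix is

    F_mn = Σ_i rqe_i² / (rqe_i·f(θ) + v_i) · ∂f/∂θ_m · ∂f/∂θ_n

evaluated with the same analytic Jacobians, on the same 11-px window the
fitter uses (the bound should describe the estimator actually run; a
larger window tightens it negligibly). Bounds are the square roots of
the inverse-Fisher diagonal; both the 4- and 5-parameter sets are
supported. On a striped sensor the bound depends on the emitter's
position, so figure-style outputs average (and also report the median
of) the bound over all simulated emitter positions.

## Experiments and their scales

All three experiment protocols run on the reference synthetic sensor and
derive every random stream from one seed, so they are reproducible
bit-for-bit. The study conditions are the reference SMLM regime: 250
photons/frame per emitter, 20 photons/px background, σ = 1.5 px at
100 nm pixels, blinking off-time 2 frames.

* **Detection bias** (grid emitters, 20 px spacing with uniform
  sub-pixel jitter, 320×320 px → 256 emitters, 300 frames): every
  emitter is scored in every frame; the threshold is the mean
  significance; localizations are split at the bottom/top 20% of the
  *pixel* distribution of smoothed gain. Uncorrected pre-processing
  discards far more of the high-gain category; RQE-corrected
  pre-processing equalizes the categories (two-sample KS test).
* **Enrichment** (blinking emitters at 0.15/µm², 192×192 px, 700
  frames): full identify-and-fit pipeline with the detection threshold
  at the analytic single-emitter significance — the marginal-detection
  regime where the artifact is strongest. Because molecules are fixed
  in space, per-pixel counts are lumpy; the experiment pools
  localizations from independent replicate simulations (fresh emitter
  placements, same camera — 4 in the shipped runs) before forming
  counts, so the quintile ratio and the Pearson correlation average
  over many placements.
* **Accuracy** (grid emitters with sub-pixel jitter, 160×160 px → 64
  emitters, 500 frames, up to 8 replicates): emitters are fit at their
  known positions by all three estimators; precision is the per-emitter
  std over frames, bias is the precision-corrected RMS of the
  per-emitter mean error, `bias² = max(0, RMS² − precision²/K)` with K
  fits per emitter (the correction removes the sampling noise of the
  K-frame mean; it is switchable). Error bars are across-replicate
  standard deviations. The CRLB is averaged over the same emitter
  positions.

These sizes were chosen to keep each experiment in the minutes range on
one CPU while leaving the Monte-Carlo error well below the effects being
measured; enlarging the frames or frame counts tightens, but does not
change, the results.

## What the synthetic data do not show

The generator reproduces the *statistical* structure of a measured
sensor (variances, anti-correlation, stripe geometry) but not any real
sensor's actual spatial spectrum; artifact magnitudes on real cameras
will differ with stripe coherence. The simulator uses discrete-frame
blinking (no partial-frame emission), a constant emitter intensity, an
isotropic Gaussian PSF, and no drift, so passing tests demonstrate the
correctness and internal consistency of the algorithms under this model
— not performance on real dye photophysics, aberrated PSFs, or 3-D
data. ADU values are kept real-valued by default (integer quantization
is available as a flag); quantization noise is negligible at gain 2.

## Degenerate inputs and edge behavior

Dark movies need at least 2 frames; gain fitting flags pixels with a
degenerate abscissa as NaN; RQE computation refuses non-positive
smoothed images (too little light). Detection drops windows that leave
the frame; fitting skips edge-clipped candidates (counted); emitters
with fewer than two fits are excluded from accuracy reports (counted).
Localization count maps are analyzed on the interior (margin = the
detection window half-width) so edge effects do not distort the
counts–RQE statistics.
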