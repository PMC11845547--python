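# Methods

This note documents the models, numerical choices, and limitations of
the `fixscene` pipeline, in the order data flows through it.

## Screen geometry and units

Gaze is processed in screen pixels (origin top-left, y downward) and
converted to degrees of visual angle with a flat-screen small-angle
mapping evaluated at the screen centre (pixel pitch × viewing
distance). Within the central ±15° that centre-biased free viewing
occupies, the error of this linearization is below 1%. The default
geometry is a 24″ 1920×1080 panel at 70 cm (≈44 px/°).

## Gaze-event detection

Velocity is a five-sample central difference,
v_n = (p_{n+2}+p_{n+1}−p_{n−1}−p_{n−2})/(6Δt), exact for linear motion;
it is never computed across blink/dropout boundaries and is undefined
for the two edge samples of each valid segment. Saccade thresholds are
computed per velocity component as `multiplier × sqrt(median(v²) −
median(v)²)` — the median-based robust SD of the velocity-threshold
algorithm family — with the elliptic criterion
(v_x/θ_x)² + (v_y/θ_y)² > 1. A literal "multiplier × median speed" mode
is available (`mode="median_speed"`); on typical traces the two differ
only in the effective threshold scale. A perfectly noise-free trace has
zero robust SD; detection then requires an explicit floor threshold
(`floor_threshold`, deg/s), and the error message says so. Saccades
separated by sub-50 ms lulls are deliberately not merged.

Qualification keeps fixations of 100–2000 ms whose immediately
preceding event is a saccade of 12–100 ms duration, 1–30° amplitude,
and 30–1500°/s peak velocity; the first violated bound is recorded as
the rejection reason, so filter behaviour is auditable. Consecutive
pairs require two usable fixations separated by exactly the second
one's qualifying saccade (onset within 10 ms of the first fixation's
offset); the spectral-slope delta uses absolute slopes,
Δ = |α_n| − |α_{n−1}|.

## Scene statistics

**Gamma.** The calibration table (each RGB channel stepped 0…255 in
increments of three) is fitted per channel with L(v) = L_max·(v/255)^γ
by Levenberg–Marquardt least squares with both parameters free; the
fitted model is tabulated into a 256-entry LUT. Pixel luminance is the
sum of the three channel LUTs; patch luminance is the plain mean over
the 5° patch.

**Spectral slope.** The patch (side forced odd so the fixation pixel is
the exact centre; S ≥ 32 px required) is converted to grayscale by the
unweighted RGB mean (a 0.299/0.587/0.114 option exists), mean-
subtracted, optionally windowed, Fourier-transformed with the zero
frequency shifted to the centre, and the amplitude (√power) is averaged
over orientations into integer-radius bins. α is the OLS slope of
log amplitude on log frequency from 1 cycle/patch to 90% of Nyquist
(DC excluded; the outermost bins are dropped because the square
spectrum's corners are anisotropic). The slope is invariant to the
logarithm base and to any overall scaling of the patch.

Two genuinely open choices are config-exposed and documented here
prominently:

* the Gaussian window's "SD of π/2" is interpreted as **π/2 degrees of
  visual angle** (≈1.57°, ~63% of the patch half-width), converted to
  pixels at the patch's own pitch. No other unit makes the window
  commensurate with the 5° patch. Windowing shifts the slope estimate
  by a constant offset (the window's own spectrum convolves the
  image's); the offset is the same (within 0.03) across exponents
  0.9–1.4, so comparisons between patches are unaffected. Calibration
  tests therefore run with the window off.
* the fit range (1 cycle/patch to 0.9×Nyquist) is standard practice,
  not a published constant.

**Estimator calibration.** On synthetic images constructed with an
exact 1/f^α amplitude spectrum (white-noise phases, amplitudes set to
r^−α on the FFT grid, quantized through the monitor LUT at 35%
contrast), the estimator's mean absolute error is ≤ 0.02 for
α ∈ {0.9, 1.1, 1.4} at 256×256 (window off), within the ±0.05 band the
tests assert. The residual positive bias (~0.015–0.02) comes from
integer-radius binning (the mean of r^−α over a bin exceeds the bin
centre's value) and from the quantization noise floor at high
frequencies.

## Ocular-artifact handling

The ICA branch resamples to 256 Hz (polyphase, anti-aliased),
re-references to the mastoid average, repairs bad channels, band-passes
2–100 Hz (2nd-order Butterworth, zero-phase forward–backward — an
option for single-pass exists), and doubles the data by appending
−20…+10 ms segments around saccade onsets (cycling through events until
the appended part equals the original length). Bad channels are
kurtosis outliers beyond 4 SD of the scalp-channel population (the
statistic is configurable); more than 20% bad channels fails a quality
gate. True spherical-spline interpolation needs a montage the generic
container does not carry, so repair uses inverse-distance weighting
over the four nearest good channels when positions are provided and the
mean of good scalp channels otherwise; for the synthetic studies no
channel is ever bad, so this stand-in is exercised only by its unit
tests.

Flagging uses the saccade/fixation variance-ratio criterion: component
variance averaged over saccade windows (3 samples ≈ 11.7 ms before
saccade onset to saccade offset) divided by the average over fixation
windows (fixation onset to 3 samples before the next saccade); ratios
above 1.3 are flagged and zeroed before reconstruction through the
inverse unmixing matrix. The decomposition itself (extended Infomax in
the reference pipelines) is not reimplemented — the module accepts any
square unmixing matrix with `components = unmixing @ channels`; tests
construct known mixing matrices, which makes removal quality exactly
measurable (residual correlation with the injected ocular source
≤ 0.05, neural source preserved ≥ 0.95).

## Linear deconvolution

The event-level design has one intercept; cubic B-spline terms
(5 basis functions, knots at evenly spaced quantiles, clamped
boundaries) for saccade size, saccade angle, and fixation duration;
mean-centred linear terms for the image statistics; and treatment
coding (background = reference) for fixation category. The full spline
basis satisfies partition of unity and is collinear with the intercept,
so the column whose peak sits at the predictor median is dropped; with
this convention the per-fixation model has 1 + 3×4 + 2 + 1 = 16 event-
level columns. Saccade angle uses an ordinary spline over (−180°, 180°]
(a circular-basis option would be preferable topologically; the plain
spline matches the formula as written and is what the tests validate).
Missing predictor values are imputed with the predictor's observed mean
before centring, so an imputed event contributes zero to that term.

Time expansion replicates each design column across all lags of the
−200…+400 ms window at the analysis rate (154 lags at 256 Hz, from
round(−0.2·fs) to round(0.4·fs)); overlapping events superpose
additively and rows outside the recording are dropped. Continuous
artifact detection marks any scalp sample beyond ±250 µV, extends it to
the enclosing 1000 ms window, merges overlaps, and appends task
intervals from the event list; excluded rows remove samples, not whole
events. The sparse system (tall, ~0.1% dense) is solved per channel
with LSMR at tolerance 1e-8 (tests use 1e-12 where they assert 1e-6
agreement) and an iteration cap of 10× the column count; near-rank-
deficient systems return the minimum-norm solution with a warning. On
≤2000-row systems the solution matches a dense pseudo-inverse to 1e-6
relative error, and with zero noise and 150–400 ms inter-fixation
intervals the recovered kernels are exact to 1e-6 µV while naive epoch
averaging errs by far more than 3× the deconvolution RMSE — the reason
deconvolution is used at all.

Prediction evaluates a term at grid values (no spline extrapolation
beyond the knot span; default grid points outside the observed range
are dropped), adds every other term's observed-mean contribution
("marginals", which makes waveforms comparable to conventional FRPs and
makes results invariant to the centring convention), and baseline-
corrects over −175…−75 ms — in that order. Differences between two
waveforms of the same predictor are marginal-free by construction.

## Components and group statistics

Peaks are windowed extrema (lambda: maximum in 50–100 ms; N1: minimum
in 100–200 ms; earliest sample wins ties) with the amplitude taken as
the mean of five samples centred on the extremum (19.5 ms at 256 Hz),
clipped to the window. Subject-level QC passes a subject only if the
first positive local maximum of the grand fixation-locked average falls
at 50–150 ms. The one-way repeated-measures ANOVA uses the
Greenhouse–Geisser ε computed from the within-subject covariance matrix
(clipped to [1/(k−1), 1]; exactly 1 for k = 2, where F equals the
squared paired t), generalized
η²_G = SS_effect/(SS_effect+SS_subjects+SS_error), and is implemented
vectorised so that 2,000-replicate null calibrations run in
milliseconds; a unit test cross-checks F, p, ε, and η²_G against
pingouin. Follow-up paired t tests are Benjamini–Hochberg adjusted
within each comparison family; Cohen's d is the paired d_z (mean
difference over SD of differences — the d_av variant differs and no
choice can be validated against restricted raw data). Under an
exchangeable null (33 subjects × 4 levels × 2,000 replicates) the
GG-corrected ANOVA rejects at 0.043 and the BH family commits any false
discovery at 0.047 — both within the 0.05 ± 0.01 calibration band; GG
correction is known to be mildly conservative under exact sphericity.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not the physics of any renderer or amplifier:

* **Fixation durations**: lognormal with mean 330.88 ms and CV 0.45
  (right-skewed, clipped to 80–2500 ms); only the mean/SD of real data
  are published, so the family is a modelling choice.
* **Saccades**: gamma-distributed amplitudes with mean 4.86° (shape 3,
  clipped 0.5–25°), horizontal-biased directions, minimum-jerk
  trajectories whose durations follow the saturating main sequence
  V_peak = 500·(1 − e^(−A/5°)) °/s, giving ≈29 ms at the mean
  amplitude. The fixation walk stays inside a central box (margin 12%
  of the smaller screen dimension), emulating the centre bias of free
  viewing and keeping 5° patches on-screen.
* **Blinks**: 100–400 ms invalid gaps inserted between a fixation and
  the next saccade at ~4/min.
* **Tracker noise**: white positional jitter, SD 0.03° (≈ the spatial
  precision of research trackers); 0 gives noise-free traces.
* **Scenes**: gray frames with exact power-law spectra (above);
  object masks are threshold sets of a very smooth random field,
  giving compact blobs of the requested coverage.
* **EEG**: each qualified fixation contributes Gaussian-bump kernels —
  lambda at 75 ms (σ 12 ms, +6 µV, occipital topography) and N1 at
  140 ms (σ 18 ms, −3 µV) — scaled by the product of per-predictor
  multipliers, plus per-channel 1/f noise normalized to an exact RMS
  (default 6 µV, the lambda kernel peak). The signal is exactly linear
  in the kernel base amplitudes. Default effect directions: lambda
  grows with saccade amplitude (saturating), with lower patch
  luminance, and on object fixations; N1 grows with high-spatial-
  frequency content (less negative α).

**Effect sizing (power analysis).** Recovery benchmarks must inject
effects the estimator can resolve at the benchmark's scale. At 10
subjects × 800 fixations with 6 µV noise, the group-level sampling SD
of the deconvolved effect slope is ≈0.21 µV per unit α (N1) and
≈0.0045 µV per cd/m² (lambda) — set by the in-band noise, the
predictor spreads (σ_α ≈ 0.15, σ_L ≈ 7 cd/m²), and the event count,
and essentially independent of the injected effect. The default
multiplier slopes (−2.0 per unit |α| on N1; −0.022 per cd/m² on
lambda) are therefore sized so a 10% relative error corresponds to
≥2.5 of those SDs, making the recovery tests informative about bias
rather than dominated by sampling noise. The recovered slope is
compared against an *injected* slope computed by pushing the known
truth through the identical measurement operator (kernel × mean of the
other multipliers, baseline correction, 5-sample windowed peak), so
the two numbers share every systematic factor except the estimation
itself.

## What passing tests do and do not show

The generator's noise is spatially and temporally independent across
channels apart from its 1/f spectrum; real EEG noise is spatially
correlated, non-stationary, and contains line noise and muscle
activity. Predictors are drawn independently per fixation, whereas real
scene statistics are autocorrelated along the scanpath and correlated
with saccade metrics. Saccade-locked spike potentials enter the ICA
tests as constructed sources, not as output of a real Infomax
decomposition. Recovery results therefore validate the *estimators and
their implementation* — overlap correction, spline coding, marginal
reconstruction, peak measurement, error-rate calibration — not the
field's ability to detect these effects in any particular dataset.

## Known limitations

* No circular spline for saccade angle by default; no mixed-effects or
  regularized deconvolution; fixed-effects group aggregation only.
* Bad-channel interpolation is distance-weighted, not spherical-spline.
* The generator has no pupil signal, head movement, smooth pursuit, or
  within-fixation scene motion (frames are static per fixation).
* Patch statistics assume square pixels and a single viewing distance.
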