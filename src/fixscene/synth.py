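"""Synthetic study generator: scenes, calibration, gaze, and EEG.

Every stage of the analysis can be exercised against known ground
truth: scene frames are built with an exact power-law amplitude
spectrum, monitor calibration tables follow a known gamma, gaze traces
alternate fixations and main-sequence saccades with the durations and
amplitudes typical of free viewing (fixations ~330 ms, saccades
~4.9 deg), and continuous EEG is formed by superposing fixation-locked
lambda/N1 kernels whose amplitudes depend on the per-fixation
predictors, plus 1/f noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .eeg import EEGRecording, OCCIPITAL_ROI, SCALP_64, default_labels
from .events import GazeTrace
from .frames import SceneFrame
from .geometry import DEFAULT_GEOMETRY, ScreenGeometry
from .scenestats import CalibrationTable, GammaLUT

# ---------------------------------------------------------------------------
# scene frames

def powerlaw_field(alpha: float, size: tuple[int, int],
                   rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-RMS field with amplitude spectrum ~ 1/f^alpha.

    White Gaussian noise supplies the (Hermitian) phase field; the
    amplitude at each non-DC frequency is set exactly to r^-alpha with
    r the radial frequency in cycles/image, so the construction is a
    direct inverse transform of the target spectrum.
    """
    h, w = size
    noise = rng.standard_normal(size)
    spec = np.fft.fft2(noise)
    fy = np.fft.fftfreq(h) * h
    fx = np.fft.fftfreq(w) * w
    r = np.hypot(fy[:, None], fx[None, :])
    with np.errstate(divide="ignore"):
        target = np.where(r > 0, r ** (-alpha), 0.0)
    mag = np.abs(spec)
    shaped = np.where(mag > 0, spec / np.where(mag > 0, mag, 1.0), 0.0)
    field = np.fft.ifft2(shaped * target).real
    field -= field.mean()
    rms = field.std()
    if rms == 0:
        raise ValueError("degenerate spectral field")
    return field / rms


def _blob_mask(fraction: float, size: tuple[int, int],
               rng: np.random.Generator) -> Optional[np.ndarray]:
    """Compact blobs covering ~``fraction`` of pixels (smoothed-noise
    threshold)."""
    if fraction <= 0:
        return None
    smooth = powerlaw_field(2.0, size, rng)   # very smooth -> compact blobs
    thresh = np.quantile(smooth, 1.0 - fraction)
    return smooth > thresh


def default_monitor_lut(gamma: Sequence[float] = (2.24, 2.23, 2.22),
                        max_lum: Sequence[float] | float = (30.0, 55.0, 15.0)
                        ) -> GammaLUT:
    """A plausible desktop-monitor LUT (white ~100 cd/m^2)."""
    max_lum = np.broadcast_to(np.asarray(max_lum, dtype=float), (3,))
    return GammaLUT(gamma=np.asarray(gamma, dtype=float), max_lum=max_lum)


def make_scene_frame(alpha_true: float, mean_lum: float,
                     size_px: tuple[int, int] = (256, 256),
                     object_fraction: float = 0.0,
                     seed: int = 0,
                     lut: Optional[GammaLUT] = None,
                     contrast: float = 0.35,
                     timestamp: float = 0.0,
                     frame_id: int = 0) -> SceneFrame:
    """Grayscale-textured RGB frame with a 1/f^alpha_true spectrum.

    The luminance field is ``mean_lum * (1 + contrast * z)`` with ``z``
    the unit-RMS power-law field, clipped to the monitor range and
    inverted through the LUT to gray pixel values; the frame's
    LUT-mapped mean luminance matches ``mean_lum`` within 1%.
    """
    if not 0.0 <= alpha_true <= 2.0:
        raise ValueError("alpha_true must lie in [0, 2]")
    rng = np.random.default_rng(seed)
    lut = lut or default_monitor_lut()
    total = lut.total_table            # luminance of gray (v, v, v)
    lo, hi = float(total[0]), float(total[-1])
    if not lo < mean_lum < hi:
        raise ValueError(
            f"mean_lum {mean_lum} unreachable; achievable range is "
            f"({lo:.2f}, {hi:.2f}) cd/m^2")
    z = powerlaw_field(alpha_true, size_px, rng)
    target = mean_lum * (1.0 + contrast * z)
    offset = 0.0
    for _ in range(8):
        lum = np.clip(target + offset, lo, hi)
        v = np.clip(np.searchsorted(total, lum), 0, 255)
        # searchsorted gives the right neighbour; pick the nearer entry
        v_lo = np.clip(v - 1, 0, 255)
        pick_lo = np.abs(total[v_lo] - lum) <= np.abs(total[v] - lum)
        v = np.where(pick_lo, v_lo, v)
        achieved = float(total[v].mean())
        if abs(achieved - mean_lum) <= 0.01 * mean_lum:
            break
        offset += mean_lum - achieved
    else:
        raise ValueError(
            f"mean_lum {mean_lum} unreachable after rescaling; achievable "
            f"range is approximately ({lo:.2f}, {hi:.2f}) cd/m^2")
    pixels = np.repeat(v.astype(np.uint8)[:, :, None], 3, axis=2)
    mask = _blob_mask(object_fraction, size_px, rng)
    return SceneFrame(timestamp=timestamp, pixels=pixels, object_mask=mask,
                      frame_id=frame_id)


# ---------------------------------------------------------------------------
# monitor calibration

def make_monitor_calibration(gamma_true: Sequence[float] | float = (2.24,
                                                                    2.23,
                                                                    2.22),
                             max_lum: Sequence[float] | float = (30.0, 55.0,
                                                                 15.0),
                             noise_sd: float = 0.0,
                             seed: int = 0) -> CalibrationTable:
    """Measured-luminance table: each channel stepped 0..255 by three.

    Entries follow ``max_lum * (v/255)^gamma_true`` plus Gaussian
    measurement noise, clipped at zero.
    """
    gamma = np.broadcast_to(np.asarray(gamma_true, dtype=float), (3,))
    if np.any(gamma <= 0):
        raise ValueError("gamma_true must be positive")
    mx = np.broadcast_to(np.asarray(max_lum, dtype=float), (3,))
    rng = np.random.default_rng(seed)
    v = np.arange(0, 256, 3, dtype=float)
    if v[-1] != 255:
        v = np.append(v, 255.0)
    lum = mx[None, :] * (v[:, None] / 255.0) ** gamma[None, :]
    if noise_sd > 0:
        lum = lum + rng.normal(0.0, noise_sd, size=lum.shape)
    lum = np.clip(lum, 0.0, None)
    lum[0, :] = 0.0   # v = 0 measures dark
    return CalibrationTable(pixel_values=v, luminance=lum)


# ---------------------------------------------------------------------------
# gaze traces

MAIN_SEQUENCE_VMAX = 500.0   # deg/s, saturating peak velocity
MAIN_SEQUENCE_C = 5.0        # deg, saturation constant
MINJERK_PEAK_FACTOR = 1.875  # peak velocity = 1.875 * amplitude / duration


def main_sequence_peak_velocity(amplitude_deg: np.ndarray | float
                                ) -> np.ndarray | float:
    """Saturating main-sequence relation V = Vmax (1 - exp(-A/c))."""
    return MAIN_SEQUENCE_VMAX * (1.0 - np.exp(-np.asarray(amplitude_deg)
                                              / MAIN_SEQUENCE_C))


def minimum_jerk_profile(n: int) -> np.ndarray:
    """Normalized displacement s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5."""
    tau = np.linspace(0.0, 1.0, n)
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


def make_gaze_trace(n_fixations: int,
                    fix_dur_mean_ms: float = 330.88,
                    fix_dur_cv: float = 0.45,
                    sacc_amp_mean_deg: float = 4.86,
                    blink_rate_per_min: float = 4.0,
                    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
                    seed: int = 0,
                    fs: float = 300.0,
                    jitter_sd_deg: float = 0.03,
                    margin_frac: float = 0.12
                    ) -> tuple[GazeTrace, pd.DataFrame]:
    """Alternating fixations and saccades, with ground-truth events.

    Fixation durations are lognormal (right-skewed) with the requested
    mean and coefficient of variation; saccade amplitudes are gamma
    distributed around the requested mean with durations from a
    minimum-jerk profile obeying the saturating main sequence; blink
    gaps (invalid samples, 100-400 ms) are inserted between a fixation
    and the following saccade at the requested rate. ``jitter_sd_deg``
    emulates tracker noise/fixational drift; set 0 for noise-free.

    Returns the trace and a truth table with one row per event
    (columns: type, onset, offset, duration_ms, x_px, y_px,
    amplitude_deg, angle_deg, peak_velocity_degs).
    """
    if n_fixations < 2:
        raise ValueError("need at least two fixations")
    rng = np.random.default_rng(seed)
    ppd = geometry.px_per_deg
    # the fixation walk stays inside a central box (free viewing is
    # center-biased); the default margin keeps 5-degree patches on-screen
    margin = margin_frac * min(geometry.width_px, geometry.height_px)
    box = (margin, geometry.width_px - margin,
           margin, geometry.height_px - margin)
    max_amp_px = math.hypot(box[1] - box[0], box[3] - box[2])

    sigma2 = math.log(1.0 + fix_dur_cv ** 2)
    mu = math.log(fix_dur_mean_ms) - sigma2 / 2.0
    durations_ms = rng.lognormal(mu, math.sqrt(sigma2), n_fixations)
    durations_ms = np.clip(durations_ms, 80.0, 2500.0)

    shape = 3.0
    amps = rng.gamma(shape, sacc_amp_mean_deg / shape, n_fixations - 1)
    amps = np.clip(amps, 0.5, 25.0)
    if np.any(amps * ppd > max_amp_px):
        raise ValueError("requested saccade amplitude exceeds the screen")

    mean_cycle_s = (fix_dur_mean_ms / 1000.0
                    + MINJERK_PEAK_FACTOR * sacc_amp_mean_deg
                    / main_sequence_peak_velocity(sacc_amp_mean_deg))
    p_blink = min(blink_rate_per_min / 60.0 * mean_cycle_s, 0.9)

    dt = 1.0 / fs
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    valid: list[np.ndarray] = []
    truth_rows: list[dict] = []
    pos = np.array([geometry.width_px / 2.0, geometry.height_px / 2.0])
    t_idx = 0

    def _emit(x_arr, y_arr, ok):
        nonlocal t_idx
        xs.append(x_arr)
        ys.append(y_arr)
        valid.append(np.full(x_arr.size, ok, dtype=bool))
        t0 = t_idx * dt
        t_idx += x_arr.size
        return t0, t_idx * dt

    for i in range(n_fixations):
        n_fix = max(int(round(durations_ms[i] / 1000.0 * fs)), 2)
        jit = rng.normal(0.0, jitter_sd_deg * ppd, size=(2, n_fix)) \
            if jitter_sd_deg > 0 else np.zeros((2, n_fix))
        onset, offset = _emit(pos[0] + jit[0], pos[1] + jit[1], True)
        truth_rows.append({
            "type": "fixation", "onset": onset, "offset": offset,
            "duration_ms": (offset - onset) * 1000.0,
            "x_px": pos[0], "y_px": pos[1],
            "amplitude_deg": np.nan, "angle_deg": np.nan,
            "peak_velocity_degs": np.nan})
        if i == n_fixations - 1:
            break

        if rng.uniform() < p_blink:
            n_blink = max(int(round(rng.uniform(100.0, 400.0)
                                    / 1000.0 * fs)), 2)
            nan = np.full(n_blink, np.nan)
            onset, offset = _emit(nan, nan, False)
            truth_rows.append({
                "type": "blink", "onset": onset, "offset": offset,
                "duration_ms": (offset - onset) * 1000.0,
                "x_px": np.nan, "y_px": np.nan, "amplitude_deg": np.nan,
                "angle_deg": np.nan, "peak_velocity_degs": np.nan})

        amp = float(amps[i])
        for _ in range(64):
            if rng.uniform() < 0.6:
                base = 0.0 if rng.uniform() < 0.5 else 180.0
                angle = rng.normal(base, 25.0)
            else:
                angle = rng.uniform(-180.0, 180.0)
            step = amp * ppd * np.array([math.cos(math.radians(angle)),
                                         -math.sin(math.radians(angle))])
            target = pos + step
            if box[0] <= target[0] <= box[1] and \
                    box[2] <= target[1] <= box[3]:
                break
        else:
            # aim back toward the centre with the same amplitude
            centre = np.array([geometry.width_px / 2.0,
                               geometry.height_px / 2.0])
            direction = centre - pos
            direction /= np.linalg.norm(direction)
            step = amp * ppd * direction
            target = pos + step
            angle = math.degrees(math.atan2(-step[1], step[0]))
        if angle <= -180.0:
            angle += 360.0
        elif angle > 180.0:
            angle -= 360.0

        vpeak = float(main_sequence_peak_velocity(amp))
        dur_s = MINJERK_PEAK_FACTOR * amp / vpeak
        n_sac = max(int(round(dur_s * fs)), 5)
        prof = minimum_jerk_profile(n_sac)
        onset, offset = _emit(pos[0] + (target[0] - pos[0]) * prof,
                              pos[1] + (target[1] - pos[1]) * prof, True)
        truth_rows.append({
            "type": "saccade", "onset": onset, "offset": offset,
            "duration_ms": (offset - onset) * 1000.0,
            "x_px": np.nan, "y_px": np.nan, "amplitude_deg": amp,
            "angle_deg": angle, "peak_velocity_degs": vpeak})
        pos = target

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    ok = np.concatenate(valid)
    time = np.arange(x.size) * dt
    trace = GazeTrace(time=time, x=x, y=y, valid=ok)
    truth = pd.DataFrame(truth_rows)
    return trace, truth


def draw_fixation_predictors(truth: pd.DataFrame, seed: int = 0,
                             lum_mean: float = 30.0, lum_sd: float = 7.0,
                             alpha_mean: float = -1.2, alpha_sd: float = 0.15,
                             p_object: float = 0.55) -> pd.DataFrame:
    """Attach per-fixation image statistics and category to a truth table.

    Patch luminance is Gaussian around 30 cd/m^2 (clipped to 12-55),
    the spectral slope Gaussian around -1.2 (clipped to -1.6..-0.8),
    and the fixation category Bernoulli. The preceding saccade's
    amplitude/angle/duration are copied onto each fixation row.
    """
    rng = np.random.default_rng(seed)
    truth = truth.copy()
    is_fix = truth["type"] == "fixation"
    n = int(is_fix.sum())
    truth.loc[is_fix, "mean_luminance"] = np.clip(
        rng.normal(lum_mean, lum_sd, n), 12.0, 55.0)
    truth.loc[is_fix, "alpha"] = np.clip(
        rng.normal(alpha_mean, alpha_sd, n), -1.6, -0.8)
    truth.loc[is_fix, "category"] = np.where(
        rng.uniform(size=n) < p_object, "object", "background")
    # copy preceding-saccade metrics onto each fixation row
    last_sac: dict | None = None
    for idx in truth.index:
        row = truth.loc[idx]
        if row["type"] == "saccade":
            last_sac = row
        elif row["type"] == "fixation":
            if last_sac is not None:
                truth.loc[idx, "sacc_amplitude_deg"] = \
                    last_sac["amplitude_deg"]
                truth.loc[idx, "sacc_angle_deg"] = last_sac["angle_deg"]
                truth.loc[idx, "sacc_duration_ms"] = last_sac["duration_ms"]
                truth.loc[idx, "sacc_peak_velocity_degs"] = \
                    last_sac["peak_velocity_degs"]
            else:
                truth.loc[idx, "sacc_amplitude_deg"] = np.nan
    return truth


# ---------------------------------------------------------------------------
# EEG forward model

@dataclass
class Kernel:
    """One fixation-locked response component (Gaussian bump)."""

    latency_s: float
    width_s: float
    polarity: int
    base_amplitude_uV: float
    scalp_weights: dict[str, float]

    def __post_init__(self) -> None:
        if not 0.0 < self.latency_s < 0.4:
            raise ValueError("kernel latency must lie in (0, 0.4) s")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be -1 or +1")

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Unit-amplitude component shape at times ``t`` (s post onset)."""
        return self.polarity * np.exp(
            -0.5 * ((t - self.latency_s) / self.width_s) ** 2)


@dataclass
class SimulationTruth:
    """Injected kernels, effect functions, and noise parameters.

    ``effect_functions[(component, predictor)]`` maps a predictor value
    to an amplitude multiplier (1 = no modulation); the per-event
    component amplitude is the base amplitude times the product of all
    of its multipliers. ``true_events`` carries one row per event with
    every predictor value filled on fixation rows.
    """

    kernels: dict[str, Kernel]
    effect_functions: dict[tuple[str, str], Callable[[np.ndarray],
                                                     np.ndarray]]
    noise_exponent: float = 1.0
    noise_rms_uV: float = 6.0
    true_events: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.noise_rms_uV < 0:
            raise ValueError("noise RMS must be nonnegative")
        if self.true_events is not None:
            fx = self.true_events[self.true_events["type"] == "fixation"]
            for col in ("mean_luminance", "alpha", "category",
                        "sacc_amplitude_deg"):
                if col not in fx.columns or fx[col].isna().all():
                    raise ValueError(
                        f"true fixation events missing predictor {col!r}")

    def event_amplitudes(self, events: pd.DataFrame) -> pd.DataFrame:
        """Per-fixation injected amplitude (uV) for every component."""
        fx = events[events["type"] == "fixation"]
        out = pd.DataFrame(index=fx.index)
        for name, kernel in self.kernels.items():
            amp = np.full(len(fx), kernel.base_amplitude_uV, dtype=float)
            for (comp, pred), fn in self.effect_functions.items():
                if comp != name:
                    continue
                vals = fx[_PREDICTOR_COLUMNS[pred]]
                amp = amp * np.asarray(fn(vals.to_numpy()), dtype=float)
            out[name] = amp
        return out


_PREDICTOR_COLUMNS = {
    "saccade_amplitude": "sacc_amplitude_deg",
    "mean_luminance": "mean_luminance",
    "alpha": "alpha",
    "category": "category",
}

#: Default injected effect sizes (see :func:`default_truth`). Sized so
#: that at the benchmark scale (10 subjects x 800 fixations, noise RMS
#: equal to the lambda kernel peak) each marginal slope exceeds the
#: deconvolution estimator's sampling noise by a comfortable margin
#: (a 10% relative error corresponds to >= 2.5 SD of the group-level
#: slope estimate).
LUMINANCE_SLOPE_PER_CDM2 = -0.022   # lower luminance -> larger lambda
ALPHA_N1_SLOPE_PER_UNIT = -2.0      # higher SF content -> larger N1
SACCADE_SATURATION_DEG = 5.0


def _saturating_saccade_effect(amp_deg: np.ndarray) -> np.ndarray:
    ref = 1.0 - math.exp(-4.86 / SACCADE_SATURATION_DEG)
    a = np.nan_to_num(np.asarray(amp_deg, dtype=float), nan=4.86)
    return (1.0 - np.exp(-a / SACCADE_SATURATION_DEG)) / ref


def default_truth(noise_rms_uV: float = 6.0,
                  true_events: Optional[pd.DataFrame] = None
                  ) -> SimulationTruth:
    """Study-like ground truth: lambda at 75 ms, N1 at 140 ms.

    Effect directions follow free-viewing findings: the lambda response
    grows with saccade amplitude (saturating), with lower patch
    luminance, and on object fixations; the N1 grows with high-spatial-
    frequency content (less negative spectral slope).
    """
    occ = {l: 1.0 for l in OCCIPITAL_ROI}
    post = {l: 0.5 for l in SCALP_64 if l.startswith(("PO", "P", "Iz"))}
    rest = {l: 0.1 for l in SCALP_64}
    lam_weights = {**rest, **post, **occ}
    n1_weights = {**rest, **post, **occ}
    kernels = {
        "lambda": Kernel(latency_s=0.075, width_s=0.012, polarity=+1,
                         base_amplitude_uV=6.0, scalp_weights=lam_weights),
        "n1": Kernel(latency_s=0.140, width_s=0.018, polarity=-1,
                     base_amplitude_uV=3.0, scalp_weights=n1_weights),
    }
    effects = {
        ("lambda", "saccade_amplitude"): _saturating_saccade_effect,
        ("lambda", "mean_luminance"):
            lambda v: 1.0 + LUMINANCE_SLOPE_PER_CDM2 * (v - 30.0),
        ("lambda", "category"):
            lambda v: np.where(np.asarray(v) == "object", 1.10, 1.0),
        ("n1", "alpha"):
            lambda v: 1.0 + ALPHA_N1_SLOPE_PER_UNIT * (np.abs(v) - 1.2),
    }
    return SimulationTruth(kernels=kernels, effect_functions=effects,
                           noise_rms_uV=noise_rms_uV,
                           true_events=true_events)


def one_over_f_noise(shape: tuple[int, int], exponent: float,
                     rms: float, rng: np.random.Generator) -> np.ndarray:
    """Channels x samples 1/f^exponent noise, exact per-channel RMS."""
    n_ch, n_s = shape
    if rms == 0:
        return np.zeros(shape)
    noise = rng.standard_normal(shape)
    spec = np.fft.rfft(noise, axis=1)
    f = np.fft.rfftfreq(n_s)
    with np.errstate(divide="ignore"):
        gain = np.where(f > 0, f ** (-exponent / 2.0), 0.0)
    out = np.fft.irfft(spec * gain[None, :], n=n_s, axis=1)
    out -= out.mean(axis=1, keepdims=True)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd * rms


def make_eeg(true_events: pd.DataFrame, truth: SimulationTruth,
             fs: float = 256.0, n_scalp: int = 64, seed: int = 0,
             labels: Optional[list[str]] = None,
             pad_s: float = 0.5) -> EEGRecording:
    """Superpose predictor-modulated kernels at fixation onsets + noise.

    The noise-free signal is exactly linear in the kernel base
    amplitudes; doubling them doubles the signal.
    """
    if fs not in (256.0, 2048.0, 256, 2048):
        raise ValueError("fs must be 256 or 2048 Hz")
    ev = true_events.sort_values("onset").reset_index(drop=True)
    onsets = ev.loc[ev["type"] == "fixation", "onset"].to_numpy(float)
    if onsets.size and np.any(np.diff(onsets) == 0):
        raise ValueError("fixation events with identical timestamps")
    labels = labels or default_labels(n_scalp)
    n_s = int(math.ceil((float(ev["offset"].max()) + pad_s) * fs))
    rng = np.random.default_rng(seed)
    data = one_over_f_noise((len(labels), n_s), truth.noise_exponent,
                            truth.noise_rms_uV, rng)

    amps = truth.event_amplitudes(ev)
    lag = np.arange(int(round(0.4 * fs)) + 1)
    t_lag = lag / fs
    weight_mats = {}
    for name, kernel in truth.kernels.items():
        w = np.array([kernel.scalp_weights.get(l, 0.0) for l in labels])
        weight_mats[name] = (w, kernel.waveform(t_lag))
    for row_idx, onset in zip(amps.index, onsets):
        s0 = int(round(onset * fs))
        stop = min(s0 + lag.size, n_s)
        span = stop - s0
        if span <= 0:
            continue
        for name in truth.kernels:
            w, shape = weight_mats[name]
            data[:, s0:stop] += (amps.at[row_idx, name]
                                 * np.outer(w, shape[:span]))

    rows = []
    for _, r in ev.iterrows():
        if r["type"] == "fixation":
            rows.append({"type": "fixation_onset", "onset": r["onset"],
                         "offset": np.nan})
        elif r["type"] == "saccade":
            rows.append({"type": "saccade_onset", "onset": r["onset"],
                         "offset": np.nan})
            rows.append({"type": "saccade_offset", "onset": r["offset"],
                         "offset": np.nan})
    return EEGRecording(data=data, fs=float(fs), labels=list(labels),
                        events=pd.DataFrame(rows))
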