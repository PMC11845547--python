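"""Shared continuous-EEG preprocessing steps.

These are the standard operations both EEG branches use (the ICA
training branch and the deconvolution branch): polyphase resampling,
mastoid re-referencing, statistical bad-channel detection with
interpolation, and zero-phase Butterworth band-pass filtering.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.stats import kurtosis

from .eeg import EEGRecording, MASTOIDS


def resample_recording(rec: EEGRecording, fs_new: float) -> EEGRecording:
    """Anti-aliased polyphase resampling; event times are unchanged."""
    if rec.fs == fs_new:
        return rec.copy_with()
    frac = Fraction(fs_new / rec.fs).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator,
                                axis=1)
    return rec.copy_with(data=data, fs=fs_new)


def rereference_mastoids(rec: EEGRecording) -> EEGRecording:
    """Subtract the average of the left/right mastoid channels."""
    for m in MASTOIDS:
        if m not in rec.labels:
            raise ValueError(f"mastoid channel {m} missing; cannot "
                             "re-reference")
    ref = 0.5 * (rec.data[rec.channel_index(MASTOIDS[0])]
                 + rec.data[rec.channel_index(MASTOIDS[1])])
    return rec.copy_with(data=rec.data - ref[None, :])


def detect_bad_channels(rec: EEGRecording, z_threshold: float = 4.0,
                        statistic: str = "kurtosis") -> list[int]:
    """Scalp channels whose amplitude statistic is an outlier.

    The per-channel statistic (kurtosis by default, or robust standard
    deviation) is z-scored across the scalp-channel population;
    channels beyond ``z_threshold`` standard deviations are bad.
    """
    picks = rec.scalp_picks
    if statistic == "kurtosis":
        stat = kurtosis(rec.data[picks], axis=1, fisher=True)
    elif statistic == "std":
        stat = rec.data[picks].std(axis=1)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    z = (stat - stat.mean()) / (stat.std() or 1.0)
    return [int(picks[i]) for i in np.flatnonzero(np.abs(z) > z_threshold)]


def interpolate_channels(rec: EEGRecording, bad: list[int],
                         positions: dict[str, np.ndarray] | None = None
                         ) -> EEGRecording:
    """Replace bad channels from their neighbours.

    With channel positions, inverse-distance weighting over the four
    nearest good scalp channels; without, the mean of all good scalp
    channels (a flat-weight stand-in for spherical interpolation, which
    needs a montage).
    """
    if not bad:
        return rec.copy_with()
    good = [i for i in rec.scalp_picks if i not in bad]
    if not good:
        raise ValueError("no good scalp channels left to interpolate from")
    data = rec.data.copy()
    for b in bad:
        if positions is not None and rec.labels[b] in positions:
            pb = np.asarray(positions[rec.labels[b]], dtype=float)
            dists = np.array([np.linalg.norm(
                np.asarray(positions[rec.labels[g]], float) - pb)
                for g in good])
            order = np.argsort(dists)[:4]
            w = 1.0 / np.maximum(dists[order], 1e-9)
            w /= w.sum()
            data[b] = w @ rec.data[[good[i] for i in order]]
        else:
            data[b] = rec.data[good].mean(axis=0)
    return rec.copy_with(data=data)


def bandpass(rec: EEGRecording, low_hz: float, high_hz: float,
             order: int = 2, zero_phase: bool = True) -> EEGRecording:
    """Butterworth band-pass (zero-phase forward-backward by default)."""
    nyq = rec.fs / 2.0
    sos = signal.butter(order, [low_hz / nyq, min(high_hz / nyq, 0.999)],
                        btype="bandpass", output="sos")
    if zero_phase:
        data = signal.sosfiltfilt(sos, rec.data, axis=1)
    else:
        data = signal.sosfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=data)


def preprocess(rec: EEGRecording, band: tuple[float, float],
               fs_target: float = 256.0, z_threshold: float = 4.0,
               max_bad_fraction: float = 0.2,
               positions: dict[str, np.ndarray] | None = None
               ) -> EEGRecording:
    """Resample, re-reference, repair bad channels, band-pass."""
    out = resample_recording(rec, fs_target)
    out = rereference_mastoids(out)
    bad = detect_bad_channels(out, z_threshold)
    if len(bad) > max_bad_fraction * len(out.scalp_picks):
        raise ValueError(f"{len(bad)} bad channels exceed the "
                         f"{max_bad_fraction:.0%} quality gate")
    out = interpolate_channels(out, bad, positions)
    return bandpass(out, band[0], band[1])
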