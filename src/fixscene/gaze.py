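"""Blink, saccade, and fixation detection from raw gaze samples.

Detection follows the velocity-based family of algorithms standard in
free-viewing work: gaps in tracker validity become blinks or dropouts
depending on duration; saccades are maximal runs where a smoothed
two-component velocity exceeds an adaptive, median-based threshold; the
remaining valid intervals become fixations. Qualification filters then
keep only fixations suitable for fixation-locked EEG analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .events import ConsecutivePair, EyeEvent, FixationRecord, GazeTrace
from .geometry import ScreenGeometry

BLINK_MIN_MS = 50.0
BLINK_MAX_MS = 500.0


@dataclass
class VelocityTrace:
    """Per-sample 2D eye velocity in deg/s; NaN where undefined."""

    time: np.ndarray
    vx: np.ndarray
    vy: np.ndarray

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)


def _sample_interval(time: np.ndarray) -> float:
    if time.size < 2:
        raise ValueError("need at least two samples")
    return float(np.median(np.diff(time)))


def _valid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs where ``valid`` is True."""
    runs = []
    idx = np.flatnonzero(np.diff(np.r_[0, valid.astype(int), 0]))
    for start, stop in zip(idx[::2], idx[1::2]):
        runs.append((int(start), int(stop)))
    return runs


def detect_blinks(gaze: GazeTrace) -> tuple[list[EyeEvent], list[EyeEvent]]:
    """Classify validity gaps into blinks and dropouts.

    Maximal runs of invalid samples lasting 50-500 ms are blinks
    (the stereotypical eyelid-closure gap); shorter or longer runs are
    dropouts. Returns ``(blinks, dropouts)``.
    """
    if len(gaze) == 0:
        raise ValueError("empty gaze trace")
    dt = _sample_interval(gaze.time)
    blinks: list[EyeEvent] = []
    dropouts: list[EyeEvent] = []
    for start, stop in _valid_runs(~gaze.valid):
        onset = float(gaze.time[start])
        offset = float(gaze.time[stop - 1]) + dt
        dur_ms = (offset - onset) * 1000.0
        kind = "blink" if BLINK_MIN_MS <= dur_ms <= BLINK_MAX_MS else "dropout"
        ev = EyeEvent(kind=kind, onset=onset, offset=offset)
        (blinks if kind == "blink" else dropouts).append(ev)
    return blinks, dropouts


def compute_velocity(gaze: GazeTrace,
                     geometry: ScreenGeometry) -> VelocityTrace:
    """Smoothed 2D gaze velocity in deg/s.

    Within each contiguous run of valid samples, velocity is a
    five-sample central difference,

        v_n = (p_{n+2} + p_{n+1} - p_{n-1} - p_{n-2}) / (6 dt),

    which is exact for linear motion and suppresses tracker noise.
    The first and last two samples of each run, all invalid samples,
    and runs shorter than five samples get NaN (never extrapolated
    across blink/dropout boundaries).
    """
    n = len(gaze)
    dt = _sample_interval(gaze.time)
    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    x_deg = gaze.x / geometry.px_per_deg
    y_deg = gaze.y / geometry.px_per_deg
    for start, stop in _valid_runs(gaze.valid):
        if stop - start < 5:
            continue
        xs = x_deg[start:stop]
        ys = y_deg[start:stop]
        sl = slice(start + 2, stop - 2)
        vx[sl] = (xs[4:] + xs[3:-1] - xs[1:-3] - xs[:-4]) / (6.0 * dt)
        vy[sl] = (ys[4:] + ys[3:-1] - ys[1:-3] - ys[:-4]) / (6.0 * dt)
    return VelocityTrace(time=gaze.time, vx=vx, vy=vy)


def _robust_sd(v: np.ndarray) -> float:
    """Median-based robust spread: sqrt(median(v^2) - median(v)^2)."""
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no defined velocity samples")
    var = float(np.median(v ** 2) - np.median(v) ** 2)
    return math.sqrt(max(var, 0.0))


def velocity_thresholds(velocity: VelocityTrace, multiplier: float = 6.0,
                        mode: str = "robust_sd") -> tuple[float, float]:
    """Per-component saccade-detection thresholds (deg/s).

    ``mode='robust_sd'`` (default) scales a median-based robust SD of
    each velocity component, the convention of the velocity algorithm
    this detector follows; ``mode='median_speed'`` scales the median of
    the absolute component velocity (the literal "six times the median
    velocity" reading).
    """
    if mode == "robust_sd":
        tx = multiplier * _robust_sd(velocity.vx)
        ty = multiplier * _robust_sd(velocity.vy)
    elif mode == "median_speed":
        fx = velocity.vx[np.isfinite(velocity.vx)]
        fy = velocity.vy[np.isfinite(velocity.vy)]
        tx = multiplier * float(np.median(np.abs(fx)))
        ty = multiplier * float(np.median(np.abs(fy)))
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    return tx, ty


def detect_saccades(gaze: GazeTrace, velocity: VelocityTrace,
                    geometry: ScreenGeometry, multiplier: float = 6.0,
                    min_duration_ms: float = 12.0,
                    mode: str = "robust_sd",
                    floor_threshold: Optional[float] = None
                    ) -> list[EyeEvent]:
    """Detect saccades as suprathreshold runs of the elliptic criterion.

    A sample is suprathreshold when ``(vx/tx)^2 + (vy/ty)^2 > 1`` with
    per-component thresholds from :func:`velocity_thresholds`; a saccade
    is a maximal suprathreshold run lasting at least ``min_duration_ms``.
    Runs separated by sub-50 ms lulls are kept separate (never merged).
    ``floor_threshold`` (deg/s) lower-bounds each component threshold;
    it is required when the adaptive threshold degenerates to zero
    (e.g., perfectly noise-free fixations).
    """
    tx, ty = velocity_thresholds(velocity, multiplier, mode)
    if floor_threshold is not None:
        tx = max(tx, floor_threshold)
        ty = max(ty, floor_threshold)
    if tx <= 0 or ty <= 0:
        raise ValueError(
            "adaptive velocity threshold is zero (no fixational noise); "
            "pass floor_threshold=<deg/s> to set a detection floor")
    dt = _sample_interval(gaze.time)
    crit = (velocity.vx / tx) ** 2 + (velocity.vy / ty) ** 2 > 1.0
    crit &= np.isfinite(velocity.vx)
    saccades: list[EyeEvent] = []
    for start, stop in _valid_runs(crit):
        onset = float(gaze.time[start])
        offset = float(gaze.time[stop - 1]) + dt
        if (offset - onset) * 1000.0 < min_duration_ms:
            continue
        dx = (gaze.x[stop - 1] - gaze.x[start]) / geometry.px_per_deg
        dy = (gaze.y[stop - 1] - gaze.y[start]) / geometry.px_per_deg
        amplitude = math.hypot(dx, dy)
        angle = math.degrees(math.atan2(-dy, dx))  # screen y points down
        if angle <= -180.0:
            angle += 360.0
        peak = float(np.nanmax(np.hypot(velocity.vx[start:stop],
                                        velocity.vy[start:stop])))
        saccades.append(EyeEvent(kind="saccade", onset=onset, offset=offset,
                                 amplitude=amplitude, peak_velocity=peak,
                                 angle=angle))
    return saccades


def detect_fixations(gaze: GazeTrace, saccades: Sequence[EyeEvent],
                     blinks: Sequence[EyeEvent],
                     dropouts: Sequence[EyeEvent] = (),
                     min_duration_ms: float = 50.0) -> list[EyeEvent]:
    """Fixations are maximal valid intervals between other events.

    Samples covered by a saccade, blink, or dropout are excluded; the
    remaining runs of valid samples lasting at least ``min_duration_ms``
    become fixations with centroid = mean gaze position. A saccade
    ending exactly on a sample leaves that sample to the fixation.
    """
    dt = _sample_interval(gaze.time)
    free = gaze.valid.copy()
    for ev in list(saccades) + list(blinks) + list(dropouts):
        # half-open [onset, offset): the sample at ev.offset is free
        covered = (gaze.time >= ev.onset - dt / 4) & \
                  (gaze.time < ev.offset - dt / 4)
        free &= ~covered
    fixations: list[EyeEvent] = []
    for start, stop in _valid_runs(free):
        onset = float(gaze.time[start])
        offset = float(gaze.time[stop - 1]) + dt
        if (offset - onset) * 1000.0 < min_duration_ms:
            continue
        fixations.append(EyeEvent(
            kind="fixation", onset=onset, offset=offset,
            centroid_x=float(np.mean(gaze.x[start:stop])),
            centroid_y=float(np.mean(gaze.y[start:stop]))))
    return fixations


#: Qualification bounds keeping only well-behaved fixation/saccade pairs.
QUALIFICATION_BOUNDS = {
    "fixation_duration_ms": (100.0, 2000.0),
    "saccade_duration_ms": (12.0, 100.0),
    "saccade_amplitude_deg": (1.0, 30.0),
    "saccade_peak_velocity_degs": (30.0, 1500.0),
}


def qualify_fixations(fixations: Sequence[EyeEvent],
                      saccades: Sequence[EyeEvent],
                      blinks: Sequence[EyeEvent] = (),
                      dropouts: Sequence[EyeEvent] = (),
                      bounds: dict | None = None) -> list[FixationRecord]:
    """Apply event-qualification filters, keeping records for all fixations.

    A fixation is usable iff its duration is 100-2000 ms and the event
    immediately preceding it is a saccade with duration 12-100 ms,
    amplitude 1-30 deg, and peak velocity 30-1500 deg/s.
    ``rejection_reason`` names the first failed bound.
    """
    b = dict(QUALIFICATION_BOUNDS)
    if bounds:
        b.update(bounds)
    timeline = sorted(
        list(fixations) + list(saccades) + list(blinks) + list(dropouts),
        key=lambda e: e.onset)
    records: list[FixationRecord] = []
    for i, ev in enumerate(timeline):
        if ev.kind != "fixation":
            continue
        prev = timeline[i - 1] if i > 0 else None
        rec = FixationRecord(fixation=ev,
                             prev_saccade=prev if prev is not None
                             and prev.kind == "saccade" else None)
        lo, hi = b["fixation_duration_ms"]
        if not lo <= ev.duration_ms <= hi:
            rec.rejection_reason = "duration"
        elif rec.prev_saccade is None:
            rec.rejection_reason = "no_preceding_saccade"
        else:
            sac = rec.prev_saccade
            lo, hi = b["saccade_duration_ms"]
            if not lo <= sac.duration_ms <= hi:
                rec.rejection_reason = "saccade_duration"
            else:
                lo, hi = b["saccade_amplitude_deg"]
                if not lo <= sac.amplitude <= hi:
                    rec.rejection_reason = "amplitude"
                else:
                    lo, hi = b["saccade_peak_velocity_degs"]
                    if not lo <= sac.peak_velocity <= hi:
                        rec.rejection_reason = "velocity"
        rec.usable = rec.rejection_reason is None
        records.append(rec)
    return records


def pair_consecutive(records: Sequence[FixationRecord],
                     max_gap_s: float = 0.010) -> list[ConsecutivePair]:
    """Pair temporally adjacent usable fixations (n-1, n).

    Both fixations must be usable and separated by exactly the second
    fixation's qualifying saccade (no intervening event; the saccade
    must start within ``max_gap_s`` of the first fixation's offset).
    Deltas are second minus first; the spectral-slope delta uses
    absolute slope values.
    """
    pairs: list[ConsecutivePair] = []
    for first, second in zip(records[:-1], records[1:]):
        if not (first.usable and second.usable):
            continue
        sac = second.prev_saccade
        if sac is None or sac.onset < first.fixation.offset - 1e-9:
            continue
        if sac.onset - first.fixation.offset > max_gap_s:
            continue
        dlum = None
        if first.mean_luminance is not None and \
                second.mean_luminance is not None:
            dlum = second.mean_luminance - first.mean_luminance
        dalpha = None
        if first.alpha is not None and second.alpha is not None:
            dalpha = abs(second.alpha) - abs(first.alpha)
        pairs.append(ConsecutivePair(first=first, second=second,
                                     delta_luminance=dlum,
                                     delta_abs_alpha=dalpha))
    return pairs
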