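"""Containers for gaze samples, ocular events, and qualified fixations."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd


@dataclass
class GazeTrace:
    """Monocular gaze samples at a nominal 300 Hz.

    ``time`` is strictly increasing, in seconds. ``x``/``y`` are screen
    pixels (origin top-left, y downward); samples with ``valid == False``
    carry no usable position (their x/y may be NaN).
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.time.size
        if not (self.x.size == self.y.size == self.valid.size == n):
            raise ValueError("time, x, y, valid must have equal length")
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return self.time.size

    @property
    def fs(self) -> float:
        """Median sampling rate (Hz)."""
        if len(self) < 2:
            raise ValueError("need at least two samples")
        return 1.0 / float(np.median(np.diff(self.time)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time, "x_px": self.x, "y_px": self.y,
            "valid": self.valid.astype(int),
        })

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GazeTrace":
        df = pd.read_csv(path, sep="\t")
        return cls(df["time_s"].to_numpy(), df["x_px"].to_numpy(),
                   df["y_px"].to_numpy(), df["valid"].to_numpy().astype(bool))


@dataclass
class EyeEvent:
    """A blink, saccade, fixation, or dropout interval.

    Saccade-only fields (amplitude, peak_velocity, angle) and
    fixation-only fields (centroid_x, centroid_y) are None when not
    applicable. ``angle`` is degrees in (-180, 180], 0 = rightward,
    counter-clockwise positive (screen y points down, so a saccade with
    decreasing y has a positive angle).
    """

    kind: str                      # blink | saccade | fixation | dropout
    onset: float                   # s
    offset: float                  # s
    amplitude: Optional[float] = None      # deg, straight-line start->end
    peak_velocity: Optional[float] = None  # deg/s
    angle: Optional[float] = None          # deg
    centroid_x: Optional[float] = None     # px
    centroid_y: Optional[float] = None     # px

    def __post_init__(self) -> None:
        if self.kind not in ("blink", "saccade", "fixation", "dropout"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.offset > self.onset:
            raise ValueError("offset must exceed onset")

    @property
    def duration_ms(self) -> float:
        return (self.offset - self.onset) * 1000.0


@dataclass
class FixationRecord:
    """One fixation with its preceding saccade: the unit of analysis.

    ``usable`` is set by qualification filtering; ``rejection_reason``
    names the first failed bound. ``mean_luminance`` (cd/m^2) and
    ``alpha`` (amplitude-spectrum slope, negative for natural scenes)
    are filled by the scene-statistics stage; ``category`` is
    'object' or 'background'.
    """

    fixation: EyeEvent
    prev_saccade: Optional[EyeEvent]
    category: str = "background"
    usable: bool = False
    rejection_reason: Optional[str] = None
    mean_luminance: Optional[float] = None
    alpha: Optional[float] = None
    fixation_duration_ms: float = field(init=False)

    def __post_init__(self) -> None:
        if self.category not in ("object", "background"):
            raise ValueError("category must be 'object' or 'background'")
        self.fixation_duration_ms = self.fixation.duration_ms


@dataclass
class ConsecutivePair:
    """Two usable fixations separated by exactly one qualifying saccade.

    Deltas are second minus first; the spectral-slope delta is taken on
    absolute slope values (|alpha_n| - |alpha_{n-1}|), so a positive
    delta means relatively more low-spatial-frequency energy on the
    second fixation.
    """

    first: FixationRecord
    second: FixationRecord
    delta_luminance: Optional[float] = None
    delta_abs_alpha: Optional[float] = None


def records_to_frame(records: Iterable[FixationRecord]) -> pd.DataFrame:
    """Tabulate fixation records (one row per record)."""
    rows = []
    for r in records:
        sac = r.prev_saccade
        rows.append({
            "fix_onset_s": r.fixation.onset,
            "fix_offset_s": r.fixation.offset,
            "fix_duration_ms": r.fixation.duration_ms,
            "x_px": r.fixation.centroid_x,
            "y_px": r.fixation.centroid_y,
            "sacc_amplitude_deg": sac.amplitude if sac else np.nan,
            "sacc_angle_deg": sac.angle if sac else np.nan,
            "sacc_peak_velocity_degs": sac.peak_velocity if sac else np.nan,
            "sacc_duration_ms": sac.duration_ms if sac else np.nan,
            "category": r.category,
            "mean_luminance_cdm2": (np.nan if r.mean_luminance is None
                                    else r.mean_luminance),
            "alpha": np.nan if r.alpha is None else r.alpha,
            "usable": r.usable,
            "reason": r.rejection_reason or "",
        })
    return pd.DataFrame(rows)


def events_to_frame(events: Iterable[EyeEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append({
            "kind": e.kind, "onset_s": e.onset, "offset_s": e.offset,
            "duration_ms": e.duration_ms,
            "amplitude_deg": np.nan if e.amplitude is None else e.amplitude,
            "peak_velocity_degs": (np.nan if e.peak_velocity is None
                                   else e.peak_velocity),
            "angle_deg": np.nan if e.angle is None else e.angle,
            "centroid_x_px": np.nan if e.centroid_x is None else e.centroid_x,
            "centroid_y_px": np.nan if e.centroid_y is None else e.centroid_y,
        })
    return pd.DataFrame(rows)
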