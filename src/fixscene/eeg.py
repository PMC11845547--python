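"""Generic continuous-EEG container with an embedded event list."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

#: 64-channel 10-10 scalp montage (Biosemi-style ordering).
SCALP_64 = [
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz", "Fpz",
    "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8", "FC6",
    "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4",
    "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
]
MASTOIDS = ["M1", "M2"]
EOG = ["EOG_LH", "EOG_RH", "EOG_UV", "EOG_LV"]
OCCIPITAL_ROI = ["O1", "Oz", "O2"]


def default_labels(n_scalp: int = 64, eog: bool = True) -> list[str]:
    """Channel labels: ``n_scalp`` scalp channels, mastoids, optional EOG.

    With fewer than 64 scalp channels, posterior channels are kept first
    (the analysis ROI is occipital), so small simulated montages always
    contain O1/Oz/O2.
    """
    if n_scalp > 64:
        raise ValueError("at most 64 scalp channels are defined")
    posterior_first = sorted(
        SCALP_64, key=lambda l: 0 if l in OCCIPITAL_ROI else 1)
    scalp = posterior_first[:n_scalp]
    # preserve canonical ordering within the selection
    scalp = [l for l in SCALP_64 if l in scalp]
    return scalp + MASTOIDS + (EOG if eog else [])


@dataclass
class EEGRecording:
    """Channels x samples voltages (microvolts) with typed events.

    ``events`` is a DataFrame with columns ``type`` (e.g.
    'fixation_onset', 'saccade_onset', 'saccade_offset',
    'task_interval'), ``onset`` (s), and ``offset`` (s; NaN for point
    events). ``bad_intervals`` is a list of (start_s, end_s) pairs.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["type", "onset", "offset"]))
    bad_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("label count must match channel count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.events) and self.events["onset"].max() > self.duration:
            raise ValueError("events fall outside the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError as exc:
            raise KeyError(f"channel {label!r} not present") from exc

    @property
    def scalp_picks(self) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels)
                         if l in SCALP_64])

    def event_onsets(self, event_type: str) -> np.ndarray:
        if len(self.events) == 0:
            return np.empty(0)
        sel = self.events["type"] == event_type
        return self.events.loc[sel, "onset"].to_numpy(dtype=float)

    def copy_with(self, **kw) -> "EEGRecording":
        out = replace(self, **kw)
        if "events" not in kw:
            out.events = self.events.copy()
        if "bad_intervals" not in kw:
            out.bad_intervals = list(self.bad_intervals)
        return out

    def to_hdf5(self, path: str | Path) -> None:
        """Layout: /data (ch x samp, uV), /fs, /labels, /events/{...}."""
        with h5py.File(path, "w") as h5:
            h5.create_dataset("data", data=self.data)
            h5.attrs["fs"] = self.fs
            h5.create_dataset(
                "labels", data=np.array(self.labels, dtype="S16"))
            grp = h5.create_group("events")
            grp.create_dataset("type", data=np.array(
                self.events["type"].astype(str), dtype="S32"))
            grp.create_dataset(
                "onset", data=self.events["onset"].to_numpy(dtype=float))
            grp.create_dataset(
                "offset", data=self.events["offset"].to_numpy(dtype=float))
            h5.create_dataset(
                "bad_intervals",
                data=np.array(self.bad_intervals, dtype=float).reshape(-1, 2))

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "EEGRecording":
        with h5py.File(path, "r") as h5:
            events = pd.DataFrame({
                "type": [t.decode() for t in h5["events/type"][()]],
                "onset": h5["events/onset"][()],
                "offset": h5["events/offset"][()],
            })
            return cls(
                data=h5["data"][()], fs=float(h5.attrs["fs"]),
                labels=[l.decode() for l in h5["labels"][()]],
                events=events,
                bad_intervals=[tuple(iv) for iv in h5["bad_intervals"][()]])


def merge_intervals(intervals: Sequence[tuple[float, float]]
                    ) -> list[tuple[float, float]]:
    """Union of possibly overlapping (start, end) intervals."""
    if not intervals:
        return []
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    merged = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(iv) for iv in merged]
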