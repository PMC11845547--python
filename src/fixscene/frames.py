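"""Scene frames: rendered RGB snapshots with timestamps and object masks."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class SceneFrame:
    """One rendered scene snapshot.

    ``pixels`` is an H x W x 3 uint8 array (0-255 per channel);
    ``object_mask`` marks object pixels (True) vs background, if known.
    """

    timestamp: float
    pixels: np.ndarray
    object_mask: Optional[np.ndarray] = None
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        self.pixels = self.pixels.astype(np.uint8)
        if not np.isfinite(self.timestamp):
            raise ValueError("timestamp must be finite")
        if self.object_mask is not None:
            self.object_mask = np.asarray(self.object_mask, dtype=bool)
            if self.object_mask.shape != self.pixels.shape[:2]:
                raise ValueError("object_mask must match frame shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def write_frames(frames: Sequence[SceneFrame], directory: str | Path
                 ) -> Path:
    """Write frames as PNG plus a TSV index (frame_id, time_s, path)."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for fr in frames:
        name = f"frame_{fr.frame_id:06d}.png"
        iio.imwrite(directory / name, fr.pixels)
        if fr.object_mask is not None:
            iio.imwrite(directory / f"mask_{fr.frame_id:06d}.png",
                        (fr.object_mask.astype(np.uint8) * 255))
        rows.append({"frame_id": fr.frame_id, "time_s": fr.timestamp,
                     "path": name})
    index = directory / "frames.tsv"
    pd.DataFrame(rows).to_csv(index, sep="\t", index=False,
                              float_format="%.6f")
    return index


def read_frames(index_path: str | Path) -> list[SceneFrame]:
    """Read frames listed in a TSV index produced by :func:`write_frames`."""
    import imageio.v3 as iio

    index_path = Path(index_path)
    df = pd.read_csv(index_path, sep="\t")
    frames = []
    for _, row in df.iterrows():
        png = index_path.parent / row["path"]
        if not png.exists():
            raise FileNotFoundError(f"missing frame file for frame_id="
                                    f"{int(row['frame_id'])}: {png}")
        pixels = iio.imread(png)
        mask_png = index_path.parent / f"mask_{int(row['frame_id']):06d}.png"
        mask = iio.imread(mask_png) > 127 if mask_png.exists() else None
        frames.append(SceneFrame(timestamp=float(row["time_s"]),
                                 pixels=pixels, object_mask=mask,
                                 frame_id=int(row["frame_id"])))
    return frames
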