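"""Simulate a small free-viewing study with known ground truth.

Writes, for each simulated subject, a 300 Hz gaze trace (TSV), the
ground-truth event table (TSV), and continuous EEG (HDF5, scratch/);
plus a shared monitor-calibration table and a set of scene frames
(PNG, scratch/) whose spectral slopes and mean luminances are known.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fixscene import synth
from fixscene.frames import write_frames
from fixscene.geometry import DEFAULT_GEOMETRY

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results" / "sim"
SCRATCH = ROOT / "scratch" / "sim"

N_SUBJECTS = 4
N_FIXATIONS = 400
SEED = 20251001


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    cal = synth.make_monitor_calibration(noise_sd=0.05, seed=SEED)
    pd.DataFrame({
        "pixel_value": cal.pixel_values,
        "lum_r": cal.luminance[:, 0], "lum_g": cal.luminance[:, 1],
        "lum_b": cal.luminance[:, 2],
    }).to_csv(RESULTS / "calibration.tsv", sep="\t", index=False,
              float_format="%.4f")

    frames = []
    alphas = np.round(np.linspace(0.9, 1.4, 6), 2)
    lums = np.linspace(22.0, 45.0, 6)
    for i, (a, lum) in enumerate(zip(alphas, lums)):
        frames.append(synth.make_scene_frame(
            a, lum,
            size_px=(DEFAULT_GEOMETRY.height_px, DEFAULT_GEOMETRY.width_px),
            object_fraction=0.3, seed=SEED + i, timestamp=i * 60.0,
            frame_id=i))
    index = write_frames(frames, SCRATCH / "frames")
    print(f"wrote {len(frames)} frames (alpha {alphas.min()}..{alphas.max()},"
          f" luminance {lums.min():.0f}..{lums.max():.0f} cd/m^2) -> {index}")

    for s in range(N_SUBJECTS):
        trace, truth = synth.make_gaze_trace(
            N_FIXATIONS, geometry=DEFAULT_GEOMETRY, seed=SEED + 100 + s)
        truth = synth.draw_fixation_predictors(truth, seed=SEED + 200 + s)
        sim_truth = synth.default_truth(noise_rms_uV=6.0, true_events=truth)
        rec = synth.make_eeg(truth, sim_truth, fs=256.0, n_scalp=8,
                             seed=SEED + 300 + s)
        sid = f"S{s:02d}"
        trace.to_tsv(RESULTS / f"{sid}_gaze.tsv")
        truth.to_csv(RESULTS / f"{sid}_truth.tsv", sep="\t", index=False,
                     float_format="%.6f")
        rec.to_hdf5(SCRATCH / f"{sid}_eeg.h5")
        fx = truth[truth["type"] == "fixation"]
        print(f"{sid}: {len(fx)} fixations (mean duration "
              f"{fx['duration_ms'].mean():.0f} ms), "
              f"{(truth['type'] == 'saccade').sum()} saccades, "
              f"EEG {rec.duration:.0f} s at {rec.fs:.0f} Hz")


if __name__ == "__main__":
    main()
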