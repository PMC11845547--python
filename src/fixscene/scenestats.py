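"""Per-fixation image statistics: patch luminance and spectral slope.

Two statistics are computed on a 5-degree square patch centred on each
fixation (roughly the fovea plus parafovea):

* **mean luminance** (cd/m^2): pixel values are mapped through a
  gamma look-up table fitted to monitor calibration measurements,
  summed across RGB per pixel, and averaged over the patch;
* **amplitude-spectrum slope** ``alpha``: the exponent of the
  ``1/f^alpha`` fall-off of the orientation-averaged Fourier amplitude
  with spatial frequency, estimated as the OLS slope of log amplitude
  on log frequency. Natural scenes give slopes near -1; more negative
  slopes mean relatively more low-spatial-frequency energy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .events import FixationRecord
from .frames import SceneFrame
from .geometry import ScreenGeometry

PATCH_DEGREES = 5.0
#: SD of the optional Gaussian window, in degrees of visual angle.
WINDOW_SD_DEGREES = np.pi / 2


@dataclass
class CalibrationTable:
    """Spectroradiometer measurements: per-channel pixel value -> cd/m^2.

    ``pixel_values`` covers 0..255 (typically in steps of three);
    ``luminance`` has shape (n_points, 3) for the R, G, B channels.
    """

    pixel_values: np.ndarray
    luminance: np.ndarray

    def __post_init__(self) -> None:
        self.pixel_values = np.asarray(self.pixel_values, dtype=float)
        self.luminance = np.asarray(self.luminance, dtype=float)
        if self.luminance.shape != (self.pixel_values.size, 3):
            raise ValueError("luminance must be (n_points, 3)")
        if self.pixel_values[0] != 0 or self.pixel_values[-1] != 255:
            raise ValueError("pixel values must span 0..255")
        if np.any(self.luminance < 0):
            raise ValueError("luminance must be nonnegative")


@dataclass
class GammaLUT:
    """Fitted gamma model and derived 256-entry LUT per RGB channel."""

    gamma: np.ndarray      # (3,)
    max_lum: np.ndarray    # (3,) cd/m^2 at pixel value 255
    table: np.ndarray = field(init=False)   # (256, 3)

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.max_lum = np.asarray(self.max_lum, dtype=float)
        v = np.arange(256)[:, None] / 255.0
        self.table = self.max_lum[None, :] * v ** self.gamma[None, :]

    def pixel_luminance(self, pixels: np.ndarray) -> np.ndarray:
        """Per-pixel luminance: LUT_R(r) + LUT_G(g) + LUT_B(b)."""
        pixels = np.asarray(pixels)
        return (self.table[pixels[..., 0], 0]
                + self.table[pixels[..., 1], 1]
                + self.table[pixels[..., 2], 2])

    @property
    def total_table(self) -> np.ndarray:
        """Luminance of gray pixels (v, v, v), 256 entries."""
        return self.table.sum(axis=1)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "gamma": self.gamma.tolist(),
            "max_lum": self.max_lum.tolist()}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GammaLUT":
        d = json.loads(Path(path).read_text())
        return cls(gamma=np.array(d["gamma"]),
                   max_lum=np.array(d["max_lum"]))


@dataclass
class Patch:
    """S x S x 3 pixel patch centred on a fixation (S odd)."""

    pixels: np.ndarray
    center: tuple[int, int]
    frame_id: int = 0

    def __post_init__(self) -> None:
        s = self.pixels.shape[0]
        if self.pixels.shape[:2] != (s, s) or s % 2 == 0:
            raise ValueError("patch must be square with odd side")


@dataclass
class RadialSpectrum:
    """Orientation-averaged amplitude spectrum (DC excluded)."""

    f: np.ndarray          # cycles/patch, strictly increasing, > 0
    amplitude: np.ndarray


def fit_gamma(calibration: CalibrationTable) -> GammaLUT:
    """Fit L(v) = Lmax * (v/255)^gamma per channel by least squares."""
    if calibration.pixel_values.size < 10:
        raise ValueError("need at least 10 calibration points per channel")
    gammas = np.empty(3)
    max_lums = np.empty(3)
    v = calibration.pixel_values / 255.0
    for ch in range(3):
        lum = calibration.luminance[:, ch]
        drops = np.diff(lum)
        tol = 0.05 * max(lum.max(), 1e-12)
        if np.any(drops < -tol):
            warnings.warn(f"channel {ch}: calibration measurements "
                          "non-monotone beyond noise tolerance")

        def model(x, lmax, g):
            return lmax * np.power(x, g)

        try:
            popt, _ = curve_fit(model, v, lum, p0=[max(lum.max(), 1.0), 2.2],
                                maxfev=20000)
        except RuntimeError as exc:  # pragma: no cover - degenerate input
            raise RuntimeError(f"gamma fit failed for channel {ch}") from exc
        max_lums[ch], gammas[ch] = popt
    return GammaLUT(gamma=gammas, max_lum=max_lums)


def match_frame(fix_onset: float, frame_times: np.ndarray) -> int:
    """Index of the frame closest in time to a fixation onset.

    Ties between two equally distant frames go to the earlier frame.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.size == 0:
        raise ValueError("frame_times is empty")
    i = int(np.searchsorted(frame_times, fix_onset))
    if i == 0:
        return 0
    if i == frame_times.size:
        return i - 1
    # earlier frame wins on a tie (<=)
    if fix_onset - frame_times[i - 1] <= frame_times[i] - fix_onset:
        return i - 1
    return i


def patch_size_px(geometry: ScreenGeometry,
                  patch_deg: float = PATCH_DEGREES) -> int:
    """Patch side in pixels, forced odd so the fixation is the centre."""
    s = int(round(patch_deg * geometry.px_per_deg))
    return s if s % 2 == 1 else s + 1


def extract_patch(frame: SceneFrame, fixation_px: tuple[float, float],
                  geometry: ScreenGeometry,
                  patch_deg: float = PATCH_DEGREES) -> Optional[Patch]:
    """Cut the fixation-centred patch, or None if it overlaps the edge.

    Edge-overlapping patches are never constructed; callers count the
    rejection in a loss report and drop the fixation from analysis.
    """
    s = patch_size_px(geometry, patch_deg)
    half = s // 2
    h, w = frame.shape
    cx = int(round(fixation_px[0]))
    cy = int(round(fixation_px[1]))
    if cx - half < 0 or cy - half < 0 or cx + half >= w or cy + half >= h:
        return None
    pixels = frame.pixels[cy - half:cy + half + 1, cx - half:cx + half + 1]
    return Patch(pixels=pixels, center=(cx, cy), frame_id=frame.frame_id)


def patch_mean_luminance(patch: Patch, lut: GammaLUT) -> float:
    """Mean over patch pixels of the RGB-summed LUT luminance."""
    return float(lut.pixel_luminance(patch.pixels).mean())


def _to_gray(pixels: np.ndarray, weights: Optional[np.ndarray]) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim == 2:
        return pixels
    if weights is None:
        return pixels.mean(axis=2)
    return pixels @ np.asarray(weights, dtype=float)


def radial_amplitude_spectrum(gray: np.ndarray,
                              fit_fraction_of_nyquist: float = 0.9
                              ) -> RadialSpectrum:
    """Orientation-averaged Fourier amplitude in integer-radius bins.

    Radius is measured in frequency pixels (= cycles/patch for a square
    patch); the DC bin is excluded and bins beyond
    ``fit_fraction_of_nyquist`` of Nyquist are dropped to avoid the
    anisotropic spectrum corners.
    """
    spec = np.fft.fftshift(np.fft.fft2(gray))
    amplitude = np.sqrt(np.abs(spec) ** 2)   # sqrt of power
    s = gray.shape[0]
    cy, cx = s // 2, gray.shape[1] // 2
    yy, xx = np.indices(gray.shape)
    r = np.rint(np.hypot(yy - cy, xx - cx)).astype(int)
    rmax = int(np.floor(fit_fraction_of_nyquist * (s // 2)))
    sums = np.bincount(r.ravel(), weights=amplitude.ravel())
    counts = np.bincount(r.ravel())
    radii = np.arange(1, min(rmax, len(sums) - 1) + 1)
    return RadialSpectrum(f=radii.astype(float),
                          amplitude=sums[radii] / counts[radii])


def amplitude_spectrum_slope(patch: Patch | np.ndarray,
                             geometry: ScreenGeometry,
                             window: bool = True,
                             demean: bool = True,
                             gray_weights: Optional[np.ndarray] = None,
                             patch_deg: float = PATCH_DEGREES
                             ) -> Optional[float]:
    """Slope of log amplitude vs log spatial frequency for one patch.

    Pipeline: grayscale (RGB mean by default), optional mean
    subtraction, optional centred 2D Gaussian window (SD = pi/2 degrees
    of visual angle converted to pixels), 2D FFT with the zero
    frequency shifted to the centre, amplitude = sqrt(power),
    orientation average into integer-radius bins, and an OLS fit of
    log amplitude on log frequency from 1 cycle/patch to 90% of
    Nyquist. Returns None for a degenerate (constant) patch.

    The slope of a log-log fit is independent of the logarithm base and
    of any overall amplitude scaling of the patch.
    """
    pixels = patch.pixels if isinstance(patch, Patch) else patch
    gray = _to_gray(pixels, gray_weights)
    if gray.shape[0] < 32:
        raise ValueError("patch too small for spectral estimation (S < 32)")
    if np.ptp(gray) == 0:
        return None
    if demean:
        gray = gray - gray.mean()
    if window:
        # SD is pi/2 degrees of visual angle; convert at the patch's own
        # pixel pitch (the patch spans patch_deg degrees) so the window
        # is identical for resampled patches
        sd_px = WINDOW_SD_DEGREES / patch_deg * gray.shape[0]
        yy, xx = np.indices(gray.shape)
        cy, cx = (gray.shape[0] - 1) / 2, (gray.shape[1] - 1) / 2
        g = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sd_px ** 2))
        gray = gray * g
    spectrum = radial_amplitude_spectrum(gray)
    good = spectrum.amplitude > 0
    if good.sum() < 2:
        return None
    logf = np.log(spectrum.f[good])
    loga = np.log(spectrum.amplitude[good])
    slope = np.polyfit(logf, loga, 1)[0]
    return float(slope)


@dataclass
class LossReport:
    """Accounting of fixations lost to edge-overlapping patches."""

    n_records: int = 0
    n_annotated: int = 0
    n_edge_rejected: int = 0
    n_degenerate: int = 0

    @property
    def edge_fraction(self) -> float:
        return self.n_edge_rejected / self.n_records if self.n_records else 0.0


def annotate_fixations(records: Sequence[FixationRecord],
                       frames: Sequence[SceneFrame], lut: GammaLUT,
                       geometry: ScreenGeometry,
                       window: bool = True) -> LossReport:
    """Fill patch statistics on usable records, in place.

    For each usable record: match the frame closest to fixation onset,
    extract the 5-degree patch, and fill mean luminance and spectral
    slope. Edge-rejected records are flagged unusable with reason
    'edge'; if the frame carries an object mask, the record's category
    is set from the mask at the fixation pixel.
    """
    frame_times = np.array([f.timestamp for f in frames])
    report = LossReport(n_records=len(records))
    for rec in records:
        if not rec.usable:
            continue
        idx = match_frame(rec.fixation.onset, frame_times)
        frame = frames[idx]
        xy = (rec.fixation.centroid_x, rec.fixation.centroid_y)
        patch = extract_patch(frame, xy, geometry)
        if patch is None:
            rec.usable = False
            rec.rejection_reason = "edge"
            report.n_edge_rejected += 1
            continue
        rec.mean_luminance = patch_mean_luminance(patch, lut)
        alpha = amplitude_spectrum_slope(patch, geometry, window=window)
        if alpha is None:
            report.n_degenerate += 1
        rec.alpha = alpha
        if frame.object_mask is not None:
            cy, cx = patch.center[1], patch.center[0]
            rec.category = ("object" if frame.object_mask[cy, cx]
                            else "background")
        report.n_annotated += 1
    return report
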