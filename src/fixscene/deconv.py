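"""Linear deconvolution of fixation-locked EEG (regression ERPs).

Free viewing produces fixations every ~300 ms while the evoked
response lasts ~600 ms, so consecutive responses overlap. Modelling
every EEG sample as the sum of lagged event contributions - a
time-expanded design matrix spanning -200..+400 ms around each
fixation onset - and solving the resulting sparse least-squares system
disentangles the overlap and yields per-lag beta waveforms for every
predictor. Splines capture the nonlinear saccade-size dependence;
continuous image statistics enter linearly; fixation category is
treatment-coded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.interpolate import BSpline
from scipy.sparse.linalg import lsmr

from .eeg import EEGRecording, merge_intervals
from .events import ConsecutivePair, FixationRecord

DEFAULT_WINDOW = (-0.200, 0.400)
DEFAULT_BASELINE = (-0.175, -0.075)

#: Post-fit evaluation grids for each continuous predictor.
MODEL1_GRIDS = {
    "sacc_size": np.arange(1.0, 15.0 + 0.5, 1.0),
    "mean_luminance": np.arange(20.0, 50.0 + 5.0, 10.0),
    "alpha": -np.arange(0.9, 1.4 + 0.05, 0.1),
}
MODEL2_GRIDS = {
    "sacc_size": np.arange(1.0, 15.0 + 0.5, 1.0),
    "delta_luminance": np.arange(-20.0, 20.0 + 5.0, 10.0),
    "delta_abs_alpha": np.arange(-0.3, 0.3 + 0.05, 0.1),
}


@dataclass
class Term:
    kind: str                       # intercept|spline|continuous|categorical
    name: str = "intercept"
    n_splines: int = 5
    levels: tuple[str, ...] = ()


@dataclass
class DesignSpec:
    """Ordered model terms, response window, and evaluation grids."""

    terms: list[Term]
    window: tuple[float, float] = DEFAULT_WINDOW
    prediction_grids: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        kinds = [t.kind for t in self.terms]
        if kinds.count("intercept") != 1:
            raise ValueError("exactly one intercept term required")
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("term names must be unique")
        if not self.window[0] < 0 < self.window[1]:
            raise ValueError("window must straddle the event onset")

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"no term named {name!r}")


def model1_spec() -> DesignSpec:
    """Per-fixation image statistics model (saccade/fixation covariates
    as 5-knot splines; luminance, spectral slope linear; category)."""
    return DesignSpec(terms=[
        Term("intercept"),
        Term("spline", "sacc_size", 5),
        Term("spline", "sacc_angle", 5),
        Term("spline", "fix_duration", 5),
        Term("continuous", "mean_luminance"),
        Term("continuous", "alpha"),
        Term("categorical", "category", levels=("background", "object")),
    ], prediction_grids=dict(MODEL1_GRIDS))


def model2_spec() -> DesignSpec:
    """Consecutive-fixation model: image statistics enter as deltas
    (second minus first fixation)."""
    return DesignSpec(terms=[
        Term("intercept"),
        Term("spline", "sacc_size", 5),
        Term("spline", "sacc_angle", 5),
        Term("spline", "fix_duration", 5),
        Term("continuous", "delta_luminance"),
        Term("continuous", "delta_abs_alpha"),
        Term("categorical", "category", levels=("background", "object")),
    ], prediction_grids=dict(MODEL2_GRIDS))


# ---------------------------------------------------------------------------
# spline basis

@dataclass
class SplineBasis:
    """Cubic B-spline basis with quantile knots and one column dropped.

    The full clamped basis satisfies partition of unity (every row sums
    to 1) and is collinear with the intercept; the column whose peak
    sits at the predictor median is dropped for identifiability.
    """

    knots: np.ndarray
    n_splines: int
    drop_index: int
    degree: int = 3

    @classmethod
    def fit(cls, values: np.ndarray, n_splines: int = 5) -> "SplineBasis":
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if np.unique(v).size < n_splines:
            raise ValueError(
                f"need at least {n_splines} distinct values for "
                f"{n_splines} splines")
        if n_splines < 4:
            raise ValueError("cubic basis needs n_splines >= 4")
        degree = 3
        n_interior = n_splines - degree - 1
        qs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
        interior = np.quantile(v, qs)
        lo, hi = float(v.min()), float(v.max())
        knots = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
        basis = cls(knots=knots, n_splines=n_splines, drop_index=0,
                    degree=degree)
        med = np.median(v)
        row = basis.full(np.array([med]))[0]
        object.__setattr__(basis, "drop_index", int(np.argmax(row)))
        return basis

    @property
    def span(self) -> tuple[float, float]:
        return float(self.knots[self.degree]), \
            float(self.knots[-self.degree - 1])

    def full(self, values: np.ndarray) -> np.ndarray:
        """(n, n_splines) basis matrix; raises outside the knot span."""
        v = np.asarray(values, dtype=float)
        lo, hi = self.span
        if np.any(v < lo - 1e-12) or np.any(v > hi + 1e-12):
            raise ValueError(
                f"value outside spline knot span [{lo:g}, {hi:g}]; "
                "extrapolation is not supported")
        v = np.clip(v, lo, hi)
        mat = BSpline.design_matrix(v, self.knots, self.degree).toarray()
        return mat

    def reduced(self, values: np.ndarray) -> np.ndarray:
        """Basis with the reference column removed."""
        mat = self.full(values)
        keep = [i for i in range(self.n_splines) if i != self.drop_index]
        return mat[:, keep]


# ---------------------------------------------------------------------------
# event tables and designs

def design_events_from_records(records: Sequence[FixationRecord]
                               ) -> pd.DataFrame:
    """Event table for the per-fixation model from usable records."""
    rows = []
    for r in records:
        if not r.usable:
            continue
        sac = r.prev_saccade
        rows.append({
            "onset": r.fixation.onset,
            "sacc_size": sac.amplitude, "sacc_angle": sac.angle,
            "fix_duration": r.fixation.duration_ms,
            "mean_luminance": (np.nan if r.mean_luminance is None
                               else r.mean_luminance),
            "alpha": np.nan if r.alpha is None else r.alpha,
            "category": r.category})
    return pd.DataFrame(rows)


def design_events_from_pairs(pairs: Sequence[ConsecutivePair]
                             ) -> pd.DataFrame:
    """Event table for the consecutive-fixation model (second onsets)."""
    rows = []
    for p in pairs:
        sac = p.second.prev_saccade
        rows.append({
            "onset": p.second.fixation.onset,
            "sacc_size": sac.amplitude, "sacc_angle": sac.angle,
            "fix_duration": p.second.fixation.duration_ms,
            "delta_luminance": (np.nan if p.delta_luminance is None
                                else p.delta_luminance),
            "delta_abs_alpha": (np.nan if p.delta_abs_alpha is None
                                else p.delta_abs_alpha),
            "category": p.second.category})
    return pd.DataFrame(rows)


def design_events_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Event table straight from a simulation truth table."""
    fx = truth[truth["type"] == "fixation"]
    return pd.DataFrame({
        "onset": fx["onset"].to_numpy(float),
        "sacc_size": fx["sacc_amplitude_deg"].to_numpy(float),
        "sacc_angle": fx["sacc_angle_deg"].to_numpy(float),
        "fix_duration": fx["duration_ms"].to_numpy(float),
        "mean_luminance": fx["mean_luminance"].to_numpy(float),
        "alpha": fx["alpha"].to_numpy(float),
        "category": fx["category"].to_numpy(),
    }).dropna(subset=["sacc_size"]).reset_index(drop=True)


@dataclass
class ColumnInfo:
    term: str
    kind: str
    detail: str    # basis index, level name, or ''


@dataclass
class DesignMatrix:
    """Event-level design with the metadata needed for prediction."""

    X: np.ndarray
    columns: list[ColumnInfo]
    spec: DesignSpec
    centers: dict[str, float]
    spline_bases: dict[str, SplineBasis]
    events: pd.DataFrame

    @property
    def n_events(self) -> int:
        return self.X.shape[0]

    def term_columns(self, name: str) -> list[int]:
        return [i for i, c in enumerate(self.columns) if c.term == name]


def build_design(events: pd.DataFrame, spec: DesignSpec) -> DesignMatrix:
    """One row per event; splines drop-one coded, continuous predictors
    mean-centered, categorical treatment-coded (first level reference).

    Missing continuous/spline values are imputed with the predictor's
    observed mean before centering; a predictor with no observed
    values at all is an error.
    """
    n = len(events)
    cols: list[np.ndarray] = []
    infos: list[ColumnInfo] = []
    centers: dict[str, float] = {}
    bases: dict[str, SplineBasis] = {}
    for term in spec.terms:
        if term.kind == "intercept":
            cols.append(np.ones(n))
            infos.append(ColumnInfo("intercept", "intercept", ""))
            continue
        if term.kind in ("spline", "continuous"):
            v = events[term.name].to_numpy(dtype=float)
            if not np.isfinite(v).any():
                raise ValueError(f"all values of {term.name!r} are missing")
            mean = float(np.nanmean(v))
            v = np.where(np.isfinite(v), v, mean)   # impute, then center
            if term.kind == "continuous":
                centers[term.name] = mean
                cols.append(v - mean)
                infos.append(ColumnInfo(term.name, "continuous", ""))
            else:
                basis = SplineBasis.fit(v, term.n_splines)
                bases[term.name] = basis
                mat = basis.reduced(v)
                for j in range(mat.shape[1]):
                    cols.append(mat[:, j])
                    infos.append(ColumnInfo(term.name, "spline", str(j)))
            continue
        if term.kind == "categorical":
            v = events[term.name].astype(str).to_numpy()
            for level in term.levels[1:]:
                cols.append((v == level).astype(float))
                infos.append(ColumnInfo(term.name, "categorical", level))
            continue
        raise ValueError(f"unknown term kind {term.kind!r}")
    return DesignMatrix(X=np.column_stack(cols), columns=infos, spec=spec,
                        centers=centers, spline_bases=bases,
                        events=events.reset_index(drop=True))


# ---------------------------------------------------------------------------
# time expansion and fitting

@dataclass
class ExpandedDesign:
    matrix: sparse.csr_matrix
    lag_times: np.ndarray
    design: DesignMatrix
    fs: float
    n_samples: int


def lag_indices(window: tuple[float, float], fs: float) -> np.ndarray:
    """Integer sample lags spanning the response window."""
    return np.arange(int(round(window[0] * fs)),
                     int(round(window[1] * fs)) + 1)


def time_expand(design: DesignMatrix, onsets: np.ndarray,
                n_samples: int, fs: float,
                window: Optional[tuple[float, float]] = None
                ) -> ExpandedDesign:
    """Replicate every design column across all lags of the window.

    Expanded column (c, lag) holds the event's design value at sample
    ``onset + lag``; overlapping events superpose additively. Rows
    falling outside the recording are dropped for that event.
    """
    window = window or design.spec.window
    onsets = np.asarray(onsets, dtype=float)
    lags = lag_indices(window, fs)
    n_lags = lags.size
    n_cols = design.X.shape[1]
    s0 = np.round(onsets * fs).astype(int)
    rows = (s0[:, None] + lags[None, :])            # (events, lags)
    ok = (rows >= 0) & (rows < n_samples)
    ev_idx, lag_idx = np.nonzero(ok)
    r = rows[ev_idx, lag_idx]
    # one block of n_lags expanded columns per design column
    data = design.X[ev_idx]                          # (nnz, n_cols)
    col_base = np.arange(n_cols) * n_lags
    rr = np.repeat(r, n_cols)
    cc = (col_base[None, :] + lag_idx[:, None]).ravel()
    vals = data.ravel()
    keep = vals != 0.0
    mat = sparse.coo_matrix((vals[keep], (rr[keep], cc[keep])),
                            shape=(n_samples, n_cols * n_lags)).tocsr()
    return ExpandedDesign(matrix=mat, lag_times=lags / fs, design=design,
                          fs=fs, n_samples=n_samples)


def detect_artifacts(rec: EEGRecording, threshold_uV: float = 250.0,
                     window_ms: float = 1000.0) -> list[tuple[float, float]]:
    """Extreme-amplitude intervals plus task intervals, merged.

    Any scalp sample beyond the voltage threshold marks a bad interval
    extended to the enclosing window; task intervals from the event
    list are appended (fixations during them are excluded from
    modelling).
    """
    picks = rec.scalp_picks
    bad = np.any(np.abs(rec.data[picks]) > threshold_uV, axis=0)
    half = window_ms / 2000.0
    intervals: list[tuple[float, float]] = []
    idx = np.flatnonzero(np.diff(np.r_[0, bad.astype(int), 0]))
    for start, stop in zip(idx[::2], idx[1::2]):
        t0 = start / rec.fs - half
        t1 = (stop - 1) / rec.fs + half
        intervals.append((max(t0, 0.0), min(t1, rec.duration)))
    if len(rec.events):
        tasks = rec.events[rec.events["type"] == "task_interval"]
        for _, row in tasks.iterrows():
            intervals.append((float(row["onset"]), float(row["offset"])))
    return merge_intervals(intervals)


@dataclass
class DeconvModelFit:
    """Per-channel beta waveforms for every design column.

    ``betas`` has shape (channels, lags, design columns), microvolts.
    """

    betas: np.ndarray
    lag_times: np.ndarray
    design: DesignMatrix
    labels: list[str]
    n_events: int
    excluded_fraction: float

    def term_betas(self, name: str) -> np.ndarray:
        """(channels, lags, term columns) slice for one term."""
        return self.betas[:, :, self.design.term_columns(name)]


def fit_deconv(expanded: ExpandedDesign, rec: EEGRecording,
               bad_intervals: Sequence[tuple[float, float]] = (),
               picks: Optional[Sequence[int]] = None,
               tol: float = 1e-8) -> DeconvModelFit:
    """Sparse least-squares solve of the time-expanded system.

    Samples inside bad intervals are excluded (events lose influence
    only where their window intersects a bad interval); each channel is
    solved independently with LSMR. Near-rank-deficient systems return
    the minimum-norm solution with a warning.
    """
    picks = (np.arange(rec.n_channels) if picks is None
             else np.asarray(list(picks)))
    good = np.ones(expanded.n_samples, dtype=bool)
    times = np.arange(expanded.n_samples) / expanded.fs
    for a, b in merge_intervals(bad_intervals):
        good &= ~((times >= a) & (times <= b))
    mat = expanded.matrix[good]
    n_cols_total = mat.shape[1]
    n_lags = expanded.lag_times.size
    n_design_cols = n_cols_total // n_lags
    betas = np.zeros((picks.size, n_lags, n_design_cols))
    maxiter = 10 * n_cols_total
    for i, ch in enumerate(picks):
        y = rec.data[ch, good]
        sol = lsmr(mat, y, atol=tol, btol=tol, maxiter=maxiter)
        x, istop = sol[0], sol[1]
        if istop not in (0, 1, 2):
            warnings.warn(f"channel {rec.labels[ch]}: LSMR stopped with "
                          f"istop={istop}; solution may be minimum-norm "
                          "due to collinear columns")
        betas[i] = x.reshape(n_design_cols, n_lags).T
    return DeconvModelFit(
        betas=betas, lag_times=expanded.lag_times, design=expanded.design,
        labels=[rec.labels[ch] for ch in picks],
        n_events=expanded.design.n_events,
        excluded_fraction=float(1.0 - good.mean()))


# ---------------------------------------------------------------------------
# prediction

@dataclass
class RegressionWaveform:
    """Reconstructed regression FRP at one predictor evaluation value."""

    predictor: str
    value: float | str
    data: np.ndarray              # channels x lags, uV
    times: np.ndarray
    labels: list[str]
    baseline_corrected: bool = False
    marginals_added: bool = False


def evaluate_at(fit: DeconvModelFit, predictor: str,
                values: Optional[Sequence] = None
                ) -> list[RegressionWaveform]:
    """Predictor-resolved waveforms before marginals and baseline.

    Continuous predictors evaluate as (value - center) x beta, splines
    through their stored basis (no extrapolation beyond the knot span),
    categorical predictors at each level. ``values`` defaults to the
    spec's prediction grid (or the term's levels).
    """
    term = fit.design.spec.term(predictor)
    col_idx = fit.design.term_columns(predictor)
    if not col_idx:
        raise KeyError(f"predictor {predictor!r} has no design columns")
    if values is None:
        if term.kind == "categorical":
            values = list(term.levels)
        else:
            values = fit.design.spec.prediction_grids.get(predictor)
            if values is None:
                raise ValueError(f"no default grid for {predictor!r}")
            if term.kind == "spline":
                # default grids may exceed the observed range; evaluating
                # a spline there would extrapolate, so those grid points
                # are dropped (explicit values still raise)
                lo, hi = fit.design.spline_bases[predictor].span
                values = [v for v in np.asarray(values, float)
                          if lo <= v <= hi]
    waveforms = []
    b = fit.betas[:, :, col_idx]                    # (ch, lags, k)
    for value in values:
        if term.kind == "continuous":
            row = np.array([float(value) - fit.design.centers[predictor]])
        elif term.kind == "spline":
            basis = fit.design.spline_bases[predictor]
            row = basis.reduced(np.array([float(value)]))[0]
        else:
            row = np.array([1.0 if str(value) == c.detail else 0.0
                            for c in (fit.design.columns[i]
                                      for i in col_idx)])
        waveforms.append(RegressionWaveform(
            predictor=predictor, value=value, data=b @ row,
            times=fit.lag_times, labels=list(fit.labels)))
    return waveforms


def add_marginals_and_baseline(waveforms: Sequence[RegressionWaveform],
                               fit: DeconvModelFit,
                               baseline: tuple[float, float] =
                               DEFAULT_BASELINE
                               ) -> list[RegressionWaveform]:
    """Add every other term's mean contribution, then baseline-correct.

    The marginal of a term is its observed-mean design row times its
    betas (continuous terms are centered so their marginal is zero;
    categorical terms contribute at observed level frequencies; splines
    at the mean basis row). Baseline correction subtracts the
    per-channel mean over the pre-onset window, so differences between
    two waveforms of the same predictor isolate that predictor's
    effect.
    """
    mean_row = fit.design.X.mean(axis=0)
    t = fit.lag_times
    base_mask = (t >= baseline[0]) & (t <= baseline[1])
    if not base_mask.any():
        raise ValueError("baseline window outside the lag range")
    out = []
    for wf in waveforms:
        own = set(fit.design.term_columns(wf.predictor))
        other = [i for i in range(mean_row.size) if i not in own]
        marginal = fit.betas[:, :, other] @ mean_row[other]
        data = wf.data + marginal
        data = data - data[:, base_mask].mean(axis=1, keepdims=True)
        out.append(RegressionWaveform(
            predictor=wf.predictor, value=wf.value, data=data,
            times=wf.times, labels=list(wf.labels),
            baseline_corrected=True, marginals_added=True))
    return out


def shuffle_predictors(events: pd.DataFrame, names: Sequence[str],
                       seed: int = 0) -> pd.DataFrame:
    """Jointly permute the named predictor columns across events.

    The named columns keep their pairing with each other but lose their
    link to the events - the null-model manipulation: any apparent
    effect of the shuffled image statistics must vanish.
    """
    out = events.reset_index(drop=True).copy()
    names = list(names)
    if not names:
        return out
    missing = [n for n in names if n not in out.columns]
    if missing:
        raise KeyError(f"unknown predictors {missing}")
    perm = np.random.default_rng(seed).permutation(len(out))
    out[names] = out[names].to_numpy()[perm]
    return out


def epoch_average(rec: EEGRecording, onsets: np.ndarray,
                  window: tuple[float, float] = DEFAULT_WINDOW
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Naive event-locked average (no overlap correction).

    Returns (channels x lags average, lag times). The comparison
    baseline for deconvolution: with overlapping events the average
    smears neighbouring responses into the window.
    """
    onsets = np.asarray(onsets, dtype=float)
    lags = lag_indices(window, rec.fs)
    acc = np.zeros((rec.n_channels, lags.size))
    count = 0
    for onset in onsets:
        idx = int(round(onset * rec.fs)) + lags
        if idx[0] < 0 or idx[-1] >= rec.n_samples:
            continue
        acc += rec.data[:, idx]
        count += 1
    if count == 0:
        raise ValueError("no event window fits inside the recording")
    return acc / count, lags / rec.fs


def waveforms_to_frame(waveforms: Sequence[RegressionWaveform]
                       ) -> pd.DataFrame:
    """Long-format export: predictor, value, channel, time_s, value_uV."""
    rows = []
    for wf in waveforms:
        for ci, label in enumerate(wf.labels):
            rows.append(pd.DataFrame({
                "predictor": wf.predictor, "level": str(wf.value),
                "channel": label, "time_s": wf.times,
                "value_uV": wf.data[ci]}))
    return pd.concat(rows, ignore_index=True)
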