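"""Component amplitudes and group-level statistics.

The lambda response (positive occipital deflection 50-100 ms after
fixation onset) and the fixation-related N1 (negative, 100-200 ms) are
measured at the occipital region of interest as the mean of five
samples centred on the extremum (19.5 ms at 256 Hz). Group analysis
uses one-way repeated-measures ANOVA with Greenhouse-Geisser
correction, generalized eta squared, and Benjamini-Hochberg-corrected
paired t tests with Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .deconv import RegressionWaveform
from .eeg import OCCIPITAL_ROI

COMPONENT_WINDOWS_MS = {"lambda": (50.0, 100.0), "n1": (100.0, 200.0)}
COMPONENT_SIGNS = {"lambda": +1, "n1": -1}
PEAK_HALF_WIDTH_SAMPLES = 2      # 5-sample average


@dataclass
class PeakAmplitude:
    component: str
    latency_ms: float
    amplitude_uV: float
    subject: Optional[str] = None
    predictor: Optional[str] = None
    value: Optional[float | str] = None


@dataclass
class AnovaResult:
    F: float
    df_num: float
    df_den: float
    epsilon: float
    p: float
    eta_g_squared: float


@dataclass
class PairedTestResult:
    pair: tuple
    t: float
    df: int
    p_raw: float
    p_fdr: float
    cohens_d: Optional[float]    # None when the difference has zero variance


def roi_waveform(waveform: RegressionWaveform,
                 roi: Sequence[str] = OCCIPITAL_ROI) -> np.ndarray:
    """Unweighted mean across the ROI channels."""
    idx = []
    for ch in roi:
        if ch not in waveform.labels:
            raise KeyError(f"ROI channel {ch!r} missing from waveform")
        idx.append(waveform.labels.index(ch))
    return waveform.data[idx].mean(axis=0)


def qc_subject(series: np.ndarray, times_s: np.ndarray,
               window_ms: tuple[float, float] = (50.0, 150.0)) -> bool:
    """Subject-level quality check on the grand fixation-locked average.

    Locates the first positive local maximum after fixation onset and
    passes iff its latency falls inside the expected lambda window.
    A series with no positive deflection fails.
    """
    t_ms = np.asarray(times_s) * 1000.0
    y = np.asarray(series, dtype=float)
    post = np.flatnonzero(t_ms > 0)
    for i in post:
        if i == 0 or i == y.size - 1:
            continue
        if y[i] > 0 and y[i] >= y[i - 1] and y[i] > y[i + 1]:
            return window_ms[0] <= t_ms[i] <= window_ms[1]
    return False


def extract_peak(series: np.ndarray, times_s: np.ndarray,
                 component: str) -> PeakAmplitude:
    """Windowed extremum with a 5-sample amplitude average.

    The extremum (maximum for the lambda response, minimum for the N1)
    is located inside the component window; amplitude is the mean of
    the extremum sample and two samples on either side, clipped to the
    samples available inside the window. Ties go to the earliest
    sample.
    """
    if component not in COMPONENT_WINDOWS_MS:
        raise KeyError(f"unknown component {component!r}")
    lo, hi = COMPONENT_WINDOWS_MS[component]
    t_ms = np.asarray(times_s) * 1000.0
    y = np.asarray(series, dtype=float)
    win = np.flatnonzero((t_ms >= lo) & (t_ms <= hi))
    if win.size == 0:
        raise ValueError(f"series does not cover the {component} window "
                         f"[{lo}, {hi}] ms")
    vals = y[win]
    if COMPONENT_SIGNS[component] > 0:
        k = int(np.argmax(vals))      # argmax/argmin take the earliest tie
    else:
        k = int(np.argmin(vals))
    peak_idx = win[k]
    a = max(peak_idx - PEAK_HALF_WIDTH_SAMPLES, win[0])
    b = min(peak_idx + PEAK_HALF_WIDTH_SAMPLES, win[-1])
    return PeakAmplitude(component=component,
                         latency_ms=float(t_ms[peak_idx]),
                         amplitude_uV=float(y[a:b + 1].mean()))


def gg_epsilon(data: np.ndarray) -> np.ndarray:
    """Greenhouse-Geisser sphericity correction factor.

    ``data`` is (..., subjects, levels); the factor is computed from
    the covariance matrix of the within-subject measures and always
    lies in [1/(k-1), 1] (exactly 1 for k = 2).
    """
    x = np.asarray(data, dtype=float)
    k = x.shape[-1]
    xc = x - x.mean(axis=-2, keepdims=True)
    n = x.shape[-2]
    S = np.swapaxes(xc, -1, -2) @ xc / (n - 1)       # (..., k, k)
    diag = np.diagonal(S, axis1=-2, axis2=-1)
    mean_diag = diag.mean(axis=-1)
    grand = S.mean(axis=(-1, -2))
    row_means = S.mean(axis=-1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * ((S ** 2).sum(axis=(-1, -2))
                     - 2 * k * (row_means ** 2).sum(axis=-1)
                     + k ** 2 * grand ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        eps = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
    return np.clip(eps, 1.0 / (k - 1), 1.0)


def rm_anova_gg(amplitudes: np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA with GG-corrected p value.

    ``amplitudes`` is a complete subjects x levels matrix (no
    imputation at the group level). Effect size is generalized eta
    squared, SS_effect / (SS_effect + SS_subjects + SS_error).
    """
    x = np.asarray(amplitudes, dtype=float)
    if x.ndim != 2:
        raise ValueError("amplitudes must be subjects x levels")
    if np.isnan(x).any():
        raise ValueError("missing cells; complete matrices required")
    n, k = x.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 levels and >= 3 subjects")
    F, ss_cond, ss_subj, ss_err = _rm_f(x)
    eps = float(gg_epsilon(x))
    df_num = eps * (k - 1)
    df_den = eps * (k - 1) * (n - 1)
    p = float(sps.f.sf(F, df_num, df_den))
    eta = ss_cond / (ss_cond + ss_subj + ss_err) \
        if (ss_cond + ss_subj + ss_err) > 0 else 0.0
    return AnovaResult(F=float(F), df_num=df_num, df_den=df_den,
                       epsilon=eps, p=p, eta_g_squared=float(eta))


def _rm_f(x: np.ndarray) -> tuple[np.ndarray, ...]:
    """F statistic and sums of squares; works on (..., n, k) stacks."""
    n, k = x.shape[-2], x.shape[-1]
    grand = x.mean(axis=(-1, -2), keepdims=True)
    subj_mean = x.mean(axis=-1, keepdims=True)
    cond_mean = x.mean(axis=-2, keepdims=True)
    ss_total = ((x - grand) ** 2).sum(axis=(-1, -2))
    ss_subj = (k * (subj_mean - grand) ** 2).sum(axis=(-1, -2))
    ss_cond = (n * (cond_mean - grand) ** 2).sum(axis=(-1, -2))
    ss_err = ss_total - ss_subj - ss_cond
    num = ss_cond / (k - 1)
    den = ss_err / ((n - 1) * (k - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(num == 0, 0.0, num / den)   # no effect -> F = 0
    return F, ss_cond, ss_subj, ss_err


def rm_anova_gg_pvalues(stack: np.ndarray) -> np.ndarray:
    """Vectorised GG-corrected p values for a (reps, n, k) stack.

    Used for null-calibration simulations where thousands of ANOVAs
    are evaluated at once.
    """
    x = np.asarray(stack, dtype=float)
    n, k = x.shape[-2], x.shape[-1]
    F = _rm_f(x)[0]
    eps = gg_epsilon(x)
    return sps.f.sf(F, eps * (k - 1), eps * (k - 1) * (n - 1))


def paired_tests_fdr(amplitudes: np.ndarray,
                     comparisons: Sequence[tuple[int, int]]
                     ) -> list[PairedTestResult]:
    """Paired t tests with Benjamini-Hochberg correction and Cohen's d.

    ``comparisons`` are ordered pairs of level indices into the
    subjects x levels matrix; d is the paired variant (mean difference
    over SD of differences) and is None (flagged) for zero-variance
    differences.
    """
    x = np.asarray(amplitudes, dtype=float)
    n = x.shape[0]
    raw_p, ts, ds = [], [], []
    for i, j in comparisons:
        diff = x[:, i] - x[:, j]
        sd = diff.std(ddof=1)
        if sd == 0:
            t, p, d = 0.0, 1.0, None
        else:
            t, p = sps.ttest_rel(x[:, i], x[:, j])
            d = float(diff.mean() / sd)
        ts.append(float(t))
        raw_p.append(float(p))
        ds.append(d)
    p_fdr = multipletests(raw_p, method="fdr_bh")[1]
    return [PairedTestResult(pair=tuple(c), t=t, df=n - 1, p_raw=p,
                             p_fdr=float(q), cohens_d=d)
            for c, t, p, q, d in zip(comparisons, ts, raw_p, p_fdr, ds)]


def peaks_to_frame(peaks: Sequence[PeakAmplitude]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject": p.subject, "predictor": p.predictor,
        "level": p.value, "component": p.component,
        "latency_ms": p.latency_ms, "amplitude_uV": p.amplitude_uV,
    } for p in peaks])


def recovery_report(peaks: pd.DataFrame,
                    injected_slopes: dict[tuple[str, str], float]
                    ) -> pd.DataFrame:
    """Injected vs recovered predictor effects on component amplitudes.

    ``peaks`` holds per-subject peak amplitudes for each (predictor,
    value, component); the recovered effect is the slope of the
    subject-mean amplitude across evaluation values, compared against
    the injected marginal slope (same units: uV per predictor unit).
    """
    rows = []
    for (comp, pred), injected in injected_slopes.items():
        sub = peaks[(peaks["component"] == comp)
                    & (peaks["predictor"] == pred)]
        if sub.empty:
            continue
        mean_amp = sub.groupby("level")["amplitude_uV"].mean()
        vals = mean_amp.index.to_numpy(dtype=float)
        recovered = float(np.polyfit(vals, mean_amp.to_numpy(), 1)[0])
        rel_err = (abs(recovered - injected) / abs(injected)
                   if injected != 0 else np.nan)
        rows.append({
            "component": comp, "predictor": pred,
            "injected_slope": injected, "recovered_slope": recovered,
            "relative_error": rel_err,
            "sign_agreement": bool(np.sign(recovered) == np.sign(injected))
            if injected != 0 else None})
    return pd.DataFrame(rows)
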