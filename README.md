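# fixscene

Analysis pipeline for **fixation-related potentials (FRPs)** in
free-viewing EEG/eye-tracking co-registration: how per-fixation scene
statistics — patch luminance and the amplitude-spectrum slope — modulate
the early visual response (the lambda response and the fixation-related
N1) once eye-movement covariates and response overlap are controlled by
linear deconvolution.

It is written for researchers who co-record gaze (≈300 Hz) and EEG
during free viewing of complex scenes and who need every stage of the
analysis to be testable: a synthetic-data module generates gaze traces,
scene frames, monitor calibration, and continuous EEG with *known*
ground truth, so detection, image statistics, artifact handling,
deconvolution, and group statistics can each be validated by parameter
recovery rather than by eye.

## What the pipeline computes

1. **Gaze events** (`fixscene.gaze`). Blinks are validity gaps of
   50–500 ms (longer/shorter gaps are dropouts). Saccades are maximal
   runs where the 5-sample-smoothed velocity exceeds an adaptive
   threshold — six times a median-based robust SD per component, with an
   elliptic two-component criterion — lasting ≥ 12 ms; fixations are the
   remaining valid intervals ≥ 50 ms. Analysis keeps fixations of
   100–2000 ms preceded by a saccade of 12–100 ms, 1–30°, 30–1500°/s.
2. **Scene statistics** (`fixscene.scenestats`). For a 5° patch centred
   on each fixation: mean luminance in cd/m² through a per-channel gamma
   LUT fitted as L(v) = L_max·(v/255)^γ, and the spectral slope α from
   the 1/f^α fall-off of the orientation-averaged Fourier amplitude —
   the OLS slope of log amplitude on log spatial frequency. Natural
   scenes give α ≈ −1; more negative α means relatively more
   low-spatial-frequency energy.
3. **Ocular ICA support** (`fixscene.ica`). Wide-band (2–100 Hz)
   training data with saccade-onset segments (−20…+10 ms) appended until
   the data doubles; components whose saccade-window variance exceeds
   their fixation-window variance by > 30% (ratio > 1.3) are flagged and
   removed. The ICA decomposition itself is supplied externally as an
   unmixing matrix.
4. **Linear deconvolution** (`fixscene.deconv`). Every EEG sample is
   modelled as the sum of lagged event contributions over a
   −200…+400 ms window around fixation onsets (regression-ERP /
   time-expanded design). The per-fixation model is, in Wilkinson
   notation,

   ```
   EEG ~ 1 + spline(sacc_size, 5) + spline(sacc_angle, 5)
           + spline(fix_duration, 5) + mean_luminance + alpha
           + cat(category)
   ```

   with a consecutive-fixation variant using Δ-luminance and Δ|α|
   between fixation n−1 and n. The sparse system is solved per channel
   (LSMR); predictor-resolved regression FRPs are reconstructed on
   standard grids (saccades 1–15°, luminance 20–50 cd/m², α −0.9…−1.4),
   other terms added as marginals, baseline −175…−75 ms.
5. **Components and statistics** (`fixscene.stats`). Lambda = positive
   occipital (O1/Oz/O2) extremum at 50–100 ms, N1 = negative extremum at
   100–200 ms; amplitude is the 5-sample (19.5 ms at 256 Hz) mean around
   the extremum. Group level: one-way repeated-measures ANOVA with
   Greenhouse–Geisser ε, generalized η²_G, and Benjamini–Hochberg
   corrected paired t tests with Cohen's d (paired variant).

## Worked example

The numbered scripts under `analysis/` run a small simulated study end
to end and write their tables under `results/sim/`:

```bash
python analysis/01_simulate_study.py    # gaze, frames, calibration, EEG
python analysis/02_detect_events.py     # detection + qualification
python analysis/03_image_statistics.py  # gamma fit, patches, slopes
python analysis/04_ocular_artifacts.py  # variance-ratio flagging demo
python analysis/05_deconvolution.py     # model fits + regression FRPs
python analysis/06_group_statistics.py  # group stats + recovery report
```

`analysis/05_deconvolution.py` prints, per simulated subject, the
reconstructed grand FRP at the occipital ROI:

```
S20251001: 393 modelled fixations; lambda +5.01 uV at 74 ms, N1 -2.84 uV at 141 ms
  shuffled-predictor null model: luminance effect -0.0098 uV per cd/m^2 (expected ~0)
```

i.e., a lambda response of ~5 µV peaking ~75 ms after fixation onset
and an N1 of ~−2.8 µV at ~140 ms; jointly shuffling the image-statistic
predictors across events destroys the luminance effect, as it must.
`analysis/06_group_statistics.py` then prints the group analysis of a
six-subject study, e.g.

```
lambda ~ mean_luminance: F(1.00,5.02) = 146.32, p = 0.0001, eps = 0.33, eta_G^2 = 0.943
   20.0 vs 30.0: t(5) = 12.28, p_fdr = 0.0001, d = 5.01
...
injected vs recovered effects:
component      predictor  injected_slope  recovered_slope  relative_error  sign_agreement
   lambda mean_luminance       -0.114868        -0.108990        0.051176            True
       n1          alpha       -5.725272        -5.338463        0.067562            True
saccade-size spline recovery RMSE = 1.2% of effect range
```

The last block is the point of the synthetic design: the effect slopes
recovered by the full pipeline (detection → deconvolution → peak
statistics) agree with the injected ground truth within a few percent,
with the correct signs, and the nonlinear (saturating) saccade-size
effect is reproduced by the spline term.

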