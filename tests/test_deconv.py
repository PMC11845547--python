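"""Time-expanded deconvolution: design, expansion, solving, prediction."""

import numpy as np
import pandas as pd
import pytest

from fixscene import deconv, eeg as ee, synth


def _events(n=60, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "onset": np.cumsum(rng.uniform(0.4, 0.8, n)) + 0.5,
        "sacc_size": rng.gamma(3.0, 1.6, n),
        "sacc_angle": rng.uniform(-180.0, 180.0, n),
        "fix_duration": rng.uniform(120.0, 900.0, n),
        "mean_luminance": rng.normal(30.0, 7.0, n),
        "alpha": rng.normal(-1.2, 0.15, n),
        "category": rng.choice(["background", "object"], n),
    })


class TestSplineBasis:
    def test_full_basis_partitions_unity(self, rng):
        v = rng.uniform(0, 10, 200)
        basis = deconv.SplineBasis.fit(v, 5)
        assert np.allclose(basis.full(v).sum(axis=1), 1.0, atol=1e-12)

    def test_reduced_basis_drops_one_column(self, rng):
        v = rng.uniform(0, 10, 50)
        basis = deconv.SplineBasis.fit(v, 5)
        assert basis.full(v).shape == (50, 5)
        assert basis.reduced(v).shape == (50, 4)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            deconv.SplineBasis.fit(np.array([1.0, 2.0, 1.0, 2.0]), 5)

    def test_extrapolation_rejected(self, rng):
        basis = deconv.SplineBasis.fit(rng.uniform(0, 10, 50), 5)
        with pytest.raises(ValueError, match="extrapolation"):
            basis.full(np.array([12.0]))

    def test_smooth_function_recovery(self, rng):
        """An OLS fit through the basis reproduces a smooth nonlinear
        function within 5% RMSE of its range at interior points."""
        x = rng.uniform(0, 10, 400)
        y = np.tanh((x - 4.0) / 2.0) + 0.3 * np.sin(x / 2.0)
        basis = deconv.SplineBasis.fit(x, 5)
        B = basis.full(x)
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        xi = np.linspace(1.0, 9.0, 50)
        yi = np.tanh((xi - 4.0) / 2.0) + 0.3 * np.sin(xi / 2.0)
        pred = basis.full(xi) @ coef
        rmse = np.sqrt(np.mean((pred - yi) ** 2))
        assert rmse <= 0.05 * np.ptp(y)


class TestBuildDesign:
    def test_model1_column_count(self):
        """1 intercept + 3 x (5-1) spline + 2 continuous + 1 categorical
        = 16 columns under the drop-one convention."""
        design = deconv.build_design(_events(), deconv.model1_spec())
        assert design.X.shape[1] == 16

    def test_missing_values_imputed_with_mean(self):
        ev = _events()
        ev.loc[3, "alpha"] = np.nan
        design = deconv.build_design(ev, deconv.model1_spec())
        col = design.term_columns("alpha")[0]
        # imputed with the observed mean, then centered -> exactly 0
        assert design.X[3, col] == pytest.approx(0.0, abs=1e-12)
        assert design.centers["alpha"] == pytest.approx(
            ev["alpha"].dropna().mean())

    def test_all_background_gives_zero_category_column(self):
        ev = _events()
        ev["category"] = "background"
        design = deconv.build_design(ev, deconv.model1_spec())
        col = design.term_columns("category")[0]
        assert np.all(design.X[:, col] == 0.0)

    def test_all_missing_predictor_is_an_error(self):
        ev = _events()
        ev["mean_luminance"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            deconv.build_design(ev, deconv.model1_spec())

    def test_continuous_columns_are_centered(self):
        design = deconv.build_design(_events(), deconv.model1_spec())
        for name in ("mean_luminance", "alpha"):
            col = design.term_columns(name)[0]
            assert design.X[:, col].mean() == pytest.approx(0.0, abs=1e-9)


def _intercept_spec():
    return deconv.DesignSpec(terms=[deconv.Term("intercept")])


class TestTimeExpansion:
    def test_lag_count_at_256hz(self):
        assert deconv.lag_indices(deconv.DEFAULT_WINDOW, 256.0).size == 154

    def test_single_event_is_a_shifted_stripe(self):
        ev = pd.DataFrame({"onset": [1.0]})
        design = deconv.build_design(ev, _intercept_spec())
        fs = 100.0
        exp = deconv.time_expand(design, ev["onset"].to_numpy(), 300, fs)
        mat = exp.matrix.toarray()
        lags = deconv.lag_indices(deconv.DEFAULT_WINDOW, fs)
        for j, lag in enumerate(lags):
            row = int(round(1.0 * fs)) + lag
            assert mat[row, j] == 1.0
        assert exp.matrix.nnz == lags.size

    def test_overlapping_events_superpose(self):
        ev = pd.DataFrame({"onset": [1.0, 1.1]})
        design = deconv.build_design(ev, _intercept_spec())
        fs = 100.0
        exp = deconv.time_expand(design, ev["onset"].to_numpy(), 300, fs)
        rowsum = np.asarray(exp.matrix.sum(axis=1)).ravel()
        overlap = (np.arange(300) / fs >= 1.1 - 0.2) & \
                  (np.arange(300) / fs <= 1.0 + 0.4)
        assert np.all(rowsum[overlap] == 2.0)

    def test_out_of_range_rows_dropped(self):
        ev = pd.DataFrame({"onset": [0.05]})    # window extends before 0
        design = deconv.build_design(ev, _intercept_spec())
        exp = deconv.time_expand(design, ev["onset"].to_numpy(), 300, 100.0)
        assert exp.matrix.nnz < deconv.lag_indices(
            deconv.DEFAULT_WINDOW, 100.0).size


class TestArtifactDetection:
    def _rec(self, n=5000, fs=256.0):
        labels = ee.default_labels(3)
        return ee.EEGRecording(data=np.zeros((len(labels), n)), fs=fs,
                               labels=labels)

    def test_clean_recording_has_no_intervals(self):
        assert deconv.detect_artifacts(self._rec()) == []

    def test_single_spike_yields_enclosing_window(self):
        rec = self._rec()
        rec.data[0, 2560] = 300.0
        ivs = deconv.detect_artifacts(rec)
        assert len(ivs) == 1
        a, b = ivs[0]
        assert b - a >= 1.0 - 1e-9
        assert a <= 10.0 <= b

    def test_nearby_spikes_merge(self):
        rec = self._rec()
        rec.data[0, 2560] = 300.0
        rec.data[1, 2560 + int(0.2 * 256)] = -300.0
        assert len(deconv.detect_artifacts(rec)) == 1

    def test_subthreshold_amplitude_ignored(self):
        rec = self._rec()
        rec.data[0, 100] = 249.0
        assert deconv.detect_artifacts(rec) == []

    def test_task_intervals_appended(self):
        rec = self._rec()
        rec.events = pd.DataFrame([{"type": "task_interval", "onset": 2.0,
                                    "offset": 5.0}])
        assert deconv.detect_artifacts(rec) == [(2.0, 5.0)]


def _kernel_recording(onsets, fs=256.0, seed=0, noise=0.0, n_scalp=3):
    """Zero-noise (by default) recording with a known injected kernel."""
    ev = pd.DataFrame([{
        "type": "fixation", "onset": t, "offset": t + 0.25,
        "duration_ms": 250.0, "mean_luminance": 30.0, "alpha": -1.2,
        "category": "background", "sacc_amplitude_deg": 4.86,
        "sacc_angle_deg": 0.0} for t in onsets])
    truth = synth.default_truth(noise_rms_uV=noise, true_events=ev)
    rec = synth.make_eeg(ev, truth, fs=fs, n_scalp=n_scalp, seed=seed)
    return rec, ev, truth


def _true_kernel(truth, lag_times, label="Oz"):
    out = np.zeros_like(lag_times)
    for k in truth.kernels.values():
        mask = lag_times >= 0
        out[mask] += (k.base_amplitude_uV * k.scalp_weights[label]
                      * k.waveform(lag_times[mask]))
    return out


class TestFitDeconv:
    def test_sparse_matches_dense_pseudoinverse(self):
        """On a small expanded system LSMR agrees with the dense
        least-squares solution to 1e-6 relative error."""
        rng = np.random.default_rng(0)
        onsets = np.cumsum(rng.uniform(0.15, 0.40, 12)) + 0.3
        rec, ev, truth = _kernel_recording(onsets, noise=1.0)
        rec.data = rec.data[:, :2000]
        spec = _intercept_spec()
        design = deconv.build_design(ev, spec)
        exp = deconv.time_expand(design, ev["onset"].to_numpy(),
                                 rec.n_samples, rec.fs)
        oz = rec.channel_index("Oz")
        fit = deconv.fit_deconv(exp, rec, picks=[oz], tol=1e-12)
        dense, *_ = np.linalg.lstsq(exp.matrix.toarray(), rec.data[oz],
                                    rcond=None)
        sparse_sol = fit.betas[0].T.ravel()
        rel = np.linalg.norm(sparse_sol - dense) / np.linalg.norm(dense)
        assert rel < 1e-6

    def test_nonoverlapping_zero_noise_recovers_kernel_exactly(self):
        onsets = np.arange(1.0, 20.0, 1.0)
        rec, ev, truth = _kernel_recording(onsets)
        design = deconv.build_design(ev, _intercept_spec())
        exp = deconv.time_expand(design, ev["onset"].to_numpy(),
                                 rec.n_samples, rec.fs)
        oz = rec.channel_index("Oz")
        fit = deconv.fit_deconv(exp, rec, picks=[oz], tol=1e-12)
        expected = _true_kernel(truth, fit.lag_times)
        assert np.max(np.abs(fit.betas[0, :, 0] - expected)) < 1e-6

    def test_overlap_corrected_while_averaging_is_not(self):
        """With 150-400 ms inter-fixation intervals and zero noise the
        deconvolved kernel is exact while naive epoch averaging carries
        the overlap error (>= 3x the deconvolution RMSE)."""
        rng = np.random.default_rng(1)
        onsets = np.cumsum(rng.uniform(0.15, 0.40, 120)) + 0.5
        rec, ev, truth = _kernel_recording(onsets)
        design = deconv.build_design(ev, _intercept_spec())
        exp = deconv.time_expand(design, ev["onset"].to_numpy(),
                                 rec.n_samples, rec.fs)
        oz = rec.channel_index("Oz")
        fit = deconv.fit_deconv(exp, rec, picks=[oz], tol=1e-12)
        expected = _true_kernel(truth, fit.lag_times)
        rmse_deconv = np.sqrt(np.mean(
            (fit.betas[0, :, 0] - expected) ** 2))
        avg, lag_t = deconv.epoch_average(rec, ev["onset"].to_numpy())
        rmse_avg = np.sqrt(np.mean((avg[oz] - expected) ** 2))
        assert np.max(np.abs(fit.betas[0, :, 0] - expected)) < 1e-6
        assert rmse_avg >= 3.0 * max(rmse_deconv, 1e-9)

    def test_bad_intervals_excluded_from_fit(self):
        onsets = np.arange(1.0, 10.0, 1.0)
        rec, ev, truth = _kernel_recording(onsets)
        rec.data[:, int(4.5 * rec.fs)] += 1e4      # giant artifact
        design = deconv.build_design(ev, _intercept_spec())
        exp = deconv.time_expand(design, ev["onset"].to_numpy(),
                                 rec.n_samples, rec.fs)
        bad = deconv.detect_artifacts(rec)
        oz = rec.channel_index("Oz")
        fit = deconv.fit_deconv(exp, rec, bad, picks=[oz], tol=1e-12)
        assert fit.excluded_fraction > 0
        expected = _true_kernel(truth, fit.lag_times)
        assert np.max(np.abs(fit.betas[0, :, 0] - expected)) < 1e-6


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(2)
    ev = _events(n=150, seed=2)
    ev["onset"] = np.cumsum(rng.uniform(0.25, 0.5, len(ev))) + 0.5
    truth = synth.default_truth(noise_rms_uV=0.0, true_events=ev.rename(
        columns={"sacc_size": "sacc_amplitude_deg"}).assign(
            type="fixation", offset=lambda d: d.onset + 0.2,
            duration_ms=200.0))
    rec = synth.make_eeg(truth.true_events, truth, n_scalp=3, seed=2)
    design = deconv.build_design(ev, deconv.model1_spec())
    exp = deconv.time_expand(design, ev["onset"].to_numpy(),
                             rec.n_samples, rec.fs)
    picks = [rec.channel_index(c) for c in ("O1", "Oz", "O2")]
    return deconv.fit_deconv(exp, rec, picks=picks), ev


class TestPrediction:

    def test_centered_value_contributes_nothing(self, fitted):
        fit, ev = fitted
        center = fit.design.centers["mean_luminance"]
        wf = deconv.evaluate_at(fit, "mean_luminance", [center])[0]
        assert np.allclose(wf.data, 0.0, atol=1e-12)

    def test_out_of_span_value_rejected(self, fitted):
        fit, _ = fitted
        with pytest.raises(ValueError, match="extrapolation"):
            deconv.evaluate_at(fit, "sacc_size", [100.0])

    def test_spline_evaluation_matches_event_row(self, fitted):
        """Evaluating the spline at an observed value reproduces that
        event's fitted contribution."""
        fit, ev = fitted
        value = float(ev["sacc_size"].iloc[10])
        wf = deconv.evaluate_at(fit, "sacc_size", [value])[0]
        cols = fit.design.term_columns("sacc_size")
        row = fit.design.X[10, cols]
        direct = fit.betas[:, :, cols] @ row
        assert np.allclose(wf.data, direct, atol=1e-9)

    def test_baseline_window_zeroed(self, fitted):
        fit, _ = fitted
        wfs = deconv.evaluate_at(fit, "mean_luminance", [25.0, 35.0])
        wfs = deconv.add_marginals_and_baseline(wfs, fit)
        t = wfs[0].times
        mask = (t >= -0.175) & (t <= -0.075)
        for wf in wfs:
            assert np.allclose(wf.data[:, mask].mean(axis=1), 0.0,
                               atol=1e-9)
            assert wf.baseline_corrected and wf.marginals_added

    def test_marginals_cancel_in_differences(self, fitted):
        fit, _ = fitted
        raw = deconv.evaluate_at(fit, "mean_luminance", [25.0, 35.0])
        full = deconv.add_marginals_and_baseline(raw, fit)
        diff_raw = raw[1].data - raw[0].data
        diff_raw -= diff_raw[:, (raw[0].times >= -0.175)
                             & (raw[0].times <= -0.075)].mean(
            axis=1, keepdims=True)
        diff_full = full[1].data - full[0].data
        assert np.allclose(diff_full, diff_raw, atol=1e-9)

    def test_category_levels_evaluate(self, fitted):
        fit, _ = fitted
        wfs = deconv.evaluate_at(fit, "category")
        assert [wf.value for wf in wfs] == ["background", "object"]
        assert np.allclose(wfs[0].data, 0.0)   # reference level

    def test_intercept_plus_marginals_matches_epoch_average(self):
        """On non-overlapping zero-noise data the marginal-added
        intercept waveform equals the baseline-corrected grand
        average."""
        onsets = np.arange(1.0, 40.0, 1.0)
        rec, ev, truth = _kernel_recording(onsets)
        design = deconv.build_design(ev, _intercept_spec())
        exp = deconv.time_expand(design, ev["onset"].to_numpy(),
                                 rec.n_samples, rec.fs)
        oz = rec.channel_index("Oz")
        fit = deconv.fit_deconv(exp, rec, picks=[oz], tol=1e-12)
        wf = [deconv.RegressionWaveform(
            predictor="intercept", value=1.0,
            data=fit.betas[:, :, fit.design.term_columns("intercept")[0]],
            times=fit.lag_times, labels=fit.labels)]
        wf = deconv.add_marginals_and_baseline(wf, fit)
        avg, lag_t = deconv.epoch_average(rec, ev["onset"].to_numpy())
        base = (lag_t >= -0.175) & (lag_t <= -0.075)
        avg_oz = avg[oz] - avg[oz][base].mean()
        assert np.allclose(wf[0].data[0], avg_oz, atol=1e-6)


class TestShuffle:
    def test_seed_reproducible(self):
        ev = _events()
        s1 = deconv.shuffle_predictors(ev, ["mean_luminance", "alpha"], 7)
        s2 = deconv.shuffle_predictors(ev, ["mean_luminance", "alpha"], 7)
        assert s1.equals(s2)

    def test_empty_name_set_is_identity(self):
        ev = _events()
        assert deconv.shuffle_predictors(ev, [], 0).equals(
            ev.reset_index(drop=True))

    def test_joint_permutation_preserves_pairing(self):
        ev = _events()
        sh = deconv.shuffle_predictors(ev, ["mean_luminance", "alpha"], 3)
        orig_pairs = set(zip(ev["mean_luminance"], ev["alpha"]))
        new_pairs = set(zip(sh["mean_luminance"], sh["alpha"]))
        assert orig_pairs == new_pairs
        assert not sh["mean_luminance"].equals(ev["mean_luminance"])
        assert sh["onset"].equals(ev["onset"])

    def test_unknown_predictor_rejected(self):
        with pytest.raises(KeyError):
            deconv.shuffle_predictors(_events(), ["nope"], 0)
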