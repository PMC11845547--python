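"""Gaze-event detection, qualification, and consecutive pairing."""

import math

import numpy as np
import pytest

from fixscene import gaze as gz, synth
from fixscene.events import EyeEvent, FixationRecord, GazeTrace

FS = 300.0


def _trace(x, y, valid=None):
    n = len(x)
    t = np.arange(n) / FS
    valid = np.ones(n, bool) if valid is None else np.asarray(valid, bool)
    return GazeTrace(t, np.asarray(x, float), np.asarray(y, float), valid)


def _gap_trace(gap_ms):
    n_gap = int(round(gap_ms / 1000 * FS))
    valid = np.r_[np.ones(100, bool), np.zeros(n_gap, bool),
                  np.ones(100, bool)]
    x = np.where(valid, 500.0, np.nan)
    return _trace(x, x, valid)


class TestBlinks:
    def test_200ms_gap_is_one_blink(self):
        blinks, dropouts = gz.detect_blinks(_gap_trace(200))
        assert len(blinks) == 1 and len(dropouts) == 0
        assert blinks[0].duration_ms == pytest.approx(200, abs=4)

    def test_600ms_gap_is_a_dropout(self):
        blinks, dropouts = gz.detect_blinks(_gap_trace(600))
        assert len(blinks) == 0 and len(dropouts) == 1

    def test_30ms_gap_is_a_dropout(self):
        blinks, dropouts = gz.detect_blinks(_gap_trace(30))
        assert len(blinks) == 0 and len(dropouts) == 1

    def test_fully_valid_trace_has_no_gap_events(self):
        blinks, dropouts = gz.detect_blinks(
            _trace(np.full(200, 1.0), np.full(200, 1.0)))
        assert blinks == [] and dropouts == []


class TestVelocity:
    def test_constant_position_zero_velocity(self, geometry):
        vel = gz.compute_velocity(_trace(np.full(50, 300.0),
                                         np.full(50, 200.0)), geometry)
        defined = np.isfinite(vel.vx)
        assert defined.sum() == 50 - 4
        assert np.allclose(vel.vx[defined], 0.0)
        assert np.allclose(vel.vy[defined], 0.0)

    def test_linear_motion_exact(self, geometry):
        """The five-sample central difference is exact for linear input."""
        t = np.arange(60) / FS
        x = 10.0 * t * geometry.px_per_deg            # 10 deg/s rightward
        vel = gz.compute_velocity(_trace(x, np.zeros(60)), geometry)
        defined = np.isfinite(vel.vx)
        assert np.allclose(vel.vx[defined], 10.0, atol=1e-9)

    def test_minimum_jerk_peak_velocity(self, geometry):
        """Smoothed peak within 5% of the analytic 1.875 A / D."""
        amp_deg, dur_s = 8.0, 0.1
        n = int(round(dur_s * FS))
        prof = synth.minimum_jerk_profile(n)
        pad = np.full(50, 0.0)
        x = np.r_[pad, amp_deg * prof * geometry.px_per_deg,
                  np.full(50, amp_deg * geometry.px_per_deg)]
        vel = gz.compute_velocity(_trace(x, np.zeros_like(x)), geometry)
        peak = np.nanmax(np.abs(vel.vx))
        assert peak == pytest.approx(1.875 * amp_deg / dur_s, rel=0.05)

    def test_velocity_undefined_across_gaps(self, geometry):
        trace = _gap_trace(200)
        vel = gz.compute_velocity(trace, geometry)
        assert np.isnan(vel.vx[~trace.valid]).all()

    def test_short_segment_undefined(self, geometry):
        valid = np.r_[np.ones(3, bool), np.zeros(60, bool),
                      np.ones(100, bool)]
        x = np.where(valid, 10.0, np.nan)
        vel = gz.compute_velocity(_trace(x, x, valid), geometry)
        assert np.isnan(vel.vx[:3]).all()


def _step_trace(speed_degs, n_move, geometry, n_pad=200, seed=0):
    """Stationary-move-stationary trace with light fixational jitter."""
    rng = np.random.default_rng(seed)
    ppd = geometry.px_per_deg
    move = speed_degs * ppd / FS * np.arange(1, n_move + 1)
    x = np.r_[np.zeros(n_pad), move, np.full(n_pad, move[-1])] + 500.0
    x += rng.normal(0, 0.02 * ppd, x.size)
    return _trace(x, np.full(x.size, 500.0)
                  + rng.normal(0, 0.02 * ppd, x.size))


class TestSaccadeDetection:
    def test_minimum_duration_rule(self, geometry):
        """A ~17 ms suprathreshold run passes the 12 ms minimum but not a
        25 ms one."""
        trace = _step_trace(120.0, 3, geometry)
        vel = gz.compute_velocity(trace, geometry)
        short_ok = gz.detect_saccades(trace, vel, geometry,
                                      min_duration_ms=12.0)
        too_strict = gz.detect_saccades(trace, vel, geometry,
                                        min_duration_ms=25.0)
        assert len(short_ok) == 1 and len(too_strict) == 0

    def test_zero_velocity_requires_floor(self, geometry):
        trace = _trace(np.full(400, 500.0), np.full(400, 500.0))
        vel = gz.compute_velocity(trace, geometry)
        with pytest.raises(ValueError, match="floor_threshold"):
            gz.detect_saccades(trace, vel, geometry)
        assert gz.detect_saccades(trace, vel, geometry,
                                  floor_threshold=30.0) == []

    def test_median_speed_mode_also_detects(self, geometry):
        trace = _step_trace(150.0, 6, geometry)
        vel = gz.compute_velocity(trace, geometry)
        sacs = gz.detect_saccades(trace, vel, geometry, mode="median_speed")
        assert len(sacs) == 1

    @pytest.mark.parametrize("theta", [0.0, 90.0, -90.0, 180.0])
    def test_angle_round_trip(self, theta, geometry):
        """A saccade constructed at angle theta is detected within 2 deg
        (0 = rightward, counter-clockwise positive, screen y down)."""
        ppd = geometry.px_per_deg
        prof = synth.minimum_jerk_profile(10)
        dx = 5 * ppd * math.cos(math.radians(theta))
        dy = -5 * ppd * math.sin(math.radians(theta))
        x = np.r_[np.full(60, 800.0), 800.0 + dx * prof,
                  np.full(60, 800.0 + dx)]
        y = np.r_[np.full(60, 500.0), 500.0 + dy * prof,
                  np.full(60, 500.0 + dy)]
        trace = _trace(x, y)
        vel = gz.compute_velocity(trace, geometry)
        sacs = gz.detect_saccades(trace, vel, geometry,
                                  floor_threshold=30.0)
        assert len(sacs) == 1
        diff = (sacs[0].angle - theta + 180.0) % 360.0 - 180.0
        assert abs(diff) <= 2.0


class TestFixationDetection:
    def test_saccade_splits_two_epochs(self, geometry):
        trace = _step_trace(150.0, 6, geometry, n_pad=120)
        vel = gz.compute_velocity(trace, geometry)
        sacs = gz.detect_saccades(trace, vel, geometry)
        fixes = gz.detect_fixations(trace, sacs, [], [])
        assert len(sacs) == 1 and len(fixes) == 2

    def test_short_epoch_is_not_a_fixation(self, geometry):
        # stable 40 ms epoch bracketed by two saccades
        trace = _step_trace(150.0, 6, geometry, n_pad=120)
        vel = gz.compute_velocity(trace, geometry)
        sacs = gz.detect_saccades(trace, vel, geometry)
        fake = EyeEvent("saccade", onset=sacs[0].offset + 0.040,
                        offset=sacs[0].offset + 0.060, amplitude=2.0,
                        peak_velocity=200.0, angle=0.0)
        fixes = gz.detect_fixations(trace, sacs + [fake], [], [])
        durations = [f.duration_ms for f in fixes]
        assert all(d >= 50.0 for d in durations)
        assert len(fixes) == 2       # the 40 ms sliver is discarded

    def test_blink_splits_an_epoch(self, geometry):
        trace = _gap_trace(200)
        blinks, dropouts = gz.detect_blinks(trace)
        fixes = gz.detect_fixations(trace, [], blinks, dropouts)
        assert len(fixes) == 2

    def test_partition_property(self, detected_noisefree):
        """Every valid sample is in at most one of saccade/fixation and
        blink samples are in neither."""
        d = detected_noisefree
        trace = d["trace"]
        count = np.zeros(len(trace), dtype=int)
        for ev in d["saccades"] + d["fixations"]:
            count += ((trace.time >= ev.onset - 1e-9)
                      & (trace.time < ev.offset - 1e-9)).astype(int)
        assert count.max() <= 1
        assert count[~trace.valid].sum() == 0


def _make_record(fix_ms=300.0, sac=(40.0, 5.0, 300.0), onset=1.0):
    sac_ev = None
    if sac is not None:
        dur, amp, vel = sac
        sac_ev = EyeEvent("saccade", onset=onset - dur / 1000.0,
                          offset=onset, amplitude=amp, peak_velocity=vel,
                          angle=0.0)
    fix = EyeEvent("fixation", onset=onset, offset=onset + fix_ms / 1000.0,
                   centroid_x=500.0, centroid_y=500.0)
    return fix, sac_ev


class TestQualification:
    def _qualify_one(self, fix_ms=300.0, sac=(40.0, 5.0, 300.0)):
        fix, sac_ev = _make_record(fix_ms, sac)
        events = [sac_ev] if sac_ev else []
        return gz.qualify_fixations([fix], events)[0]

    def test_good_record_is_usable(self):
        rec = self._qualify_one()
        assert rec.usable and rec.rejection_reason is None

    def test_short_fixation_rejected_for_duration(self):
        rec = self._qualify_one(fix_ms=80.0)
        assert not rec.usable and rec.rejection_reason == "duration"

    def test_small_saccade_rejected_for_amplitude(self):
        rec = self._qualify_one(sac=(40.0, 0.5, 300.0))
        assert not rec.usable and rec.rejection_reason == "amplitude"

    def test_slow_saccade_rejected_for_velocity(self):
        rec = self._qualify_one(sac=(40.0, 5.0, 20.0))
        assert not rec.usable and rec.rejection_reason == "velocity"

    def test_long_saccade_rejected_for_duration(self):
        rec = self._qualify_one(sac=(150.0, 5.0, 300.0))
        assert not rec.usable and rec.rejection_reason == "saccade_duration"

    def test_no_preceding_saccade(self):
        rec = self._qualify_one(sac=None)
        assert not rec.usable
        assert rec.rejection_reason == "no_preceding_saccade"

    def test_tightening_bounds_never_gains_records(self, detected_noisefree):
        d = detected_noisefree
        base = gz.qualify_fixations(d["fixations"], d["saccades"])
        n_base = sum(r.usable for r in base)
        for key, bounds in (
                ("fixation_duration_ms", (150.0, 1000.0)),
                ("saccade_amplitude_deg", (2.0, 10.0)),
                ("saccade_peak_velocity_degs", (60.0, 400.0))):
            tight = gz.qualify_fixations(d["fixations"], d["saccades"],
                                         bounds={key: bounds})
            assert sum(r.usable for r in tight) <= n_base


class TestDetectionRecovery:
    def test_recall_precision_and_timing(self, detected_noisefree):
        """>=95% recall/precision for saccades >= 1 deg; onset and offset
        errors at most one sample on the noise-free trace."""
        d = detected_noisefree
        truth = d["truth"]
        dt = 1.0 / FS
        true_sac = truth[(truth["type"] == "saccade")
                         & (truth["amplitude_deg"] >= 1.0)]
        det_on = np.array([s.onset for s in d["saccades"]])
        det_off = np.array([s.offset for s in d["saccades"]])
        hits = 0
        for _, row in true_sac.iterrows():
            j = int(np.argmin(np.abs(det_on - row["onset"])))
            if abs(det_on[j] - row["onset"]) <= dt + 1e-9:
                hits += 1
                assert abs(det_off[j] - row["offset"]) <= dt + 1e-9
        assert hits / len(true_sac) >= 0.95
        all_true_on = truth.loc[truth["type"] == "saccade",
                                "onset"].to_numpy()
        matched = sum(np.min(np.abs(all_true_on - o)) <= dt + 1e-9
                      for o in det_on)
        assert matched / len(det_on) >= 0.95


class TestConsecutivePairs:
    def _chain(self, n=3, usable=None):
        records = []
        t = 1.0
        for i in range(n):
            fix, sac = _make_record(onset=t)
            rec = gz.qualify_fixations([fix], [sac] if sac else [])[0]
            rec.mean_luminance = 30.0 + i
            rec.alpha = -1.0 - 0.1 * i
            records.append(rec)
            t += 0.340        # 300 ms fixation + 40 ms saccade
        if usable is not None:
            for i, u in enumerate(usable):
                records[i].usable = u
        return records

    def test_three_usable_fixations_give_two_pairs(self):
        pairs = gz.pair_consecutive(self._chain(3))
        assert len(pairs) == 2
        assert pairs[0].delta_luminance == pytest.approx(1.0)

    def test_unusable_middle_blocks_pairing(self):
        pairs = gz.pair_consecutive(self._chain(3, [True, False, True]))
        assert pairs == []

    def test_delta_alpha_uses_absolute_values(self):
        records = self._chain(2)
        records[0].alpha = -0.9
        records[1].alpha = -1.4
        pairs = gz.pair_consecutive(records)
        assert pairs[0].delta_abs_alpha == pytest.approx(0.5)

    def test_temporal_gap_blocks_pairing(self):
        records = self._chain(2)
        # shift the second fixation (and its saccade) 500 ms later
        records[1].prev_saccade.onset += 0.5
        records[1].prev_saccade.offset += 0.5
        records[1].fixation.onset += 0.5
        records[1].fixation.offset += 0.5
        assert gz.pair_consecutive(records) == []
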