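"""Unit and property tests of the forward-search detector and its calibration."""

import dataclasses

import numpy as np
import pytest

from oracles import brute_force_local_max, brute_force_p1, random_test_signal

from gaitsock.events import (
    AlgorithmParams,
    CalibrationInfeasible,
    NoMaximumFound,
    ThresholdNeverCrossed,
    calibrate,
    calibrate_detailed,
    detect_events,
    find_p1,
    next_local_max,
    prepare_detection_signal,
)
from gaitsock.evaluate import extract_truth
from gaitsock.synthcohort import simulate_trial
from gaitsock.timeseries import TimeSeries

FS = 1500.0


def ts(values, fs=FS, t0=0.0):
    return TimeSeries(np.asarray(values, dtype=float), fs, t0)


def gauss(t, c, amp, w):
    return amp * np.exp(-0.5 * ((t - c) / w) ** 2)


class TestFindP1:
    def test_monotone_ramp_first_crossing(self):
        t = np.arange(3001) / FS
        x = ts(-1.0 + t)  # crosses 0 at t = 1
        p1 = find_p1(x, 0.0, 0.0)
        assert 0 < p1 - 1.0 <= 1.0 / FS + 1e-12

    def test_signal_below_threshold_fails(self):
        x = ts(np.sin(np.arange(2000) / 100.0))
        with pytest.raises(ThresholdNeverCrossed):
            find_p1(x, 0.0, 5.0)

    def test_threshold_between_two_bumps(self):
        t = np.arange(4501) / FS
        x = ts(gauss(t, 1.0, 0.4, 0.08) + gauss(t, 2.0, 1.0, 0.08))
        p1 = find_p1(x, 0.0, 0.6)  # bump 1 < a1 < bump 2
        oracle = brute_force_p1(x.values, FS, 0.0, 0.0, 0.6)
        assert p1 == oracle
        assert 1.5 < p1 < 2.0  # on the rising edge of the second bump


class TestNextLocalMax:
    def test_single_bump_peak(self):
        t = np.arange(3001) / FS
        x = ts(gauss(t, 1.0, 1.0, 0.1))
        assert abs(next_local_max(x, 0.1) - 1.0) <= 1.0 / FS + 1e-12

    def test_monotone_signal_fails(self):
        x = ts(np.arange(100, dtype=float))
        with pytest.raises(NoMaximumFound):
            next_local_max(x, 0.0)

    def test_plateau_resolves_to_first_sample(self):
        v = np.array([0.0, 1.0, 2.0, 2.0, 2.0, 1.0, 0.0])
        x = ts(v, fs=10.0)
        assert next_local_max(x, 0.0) == pytest.approx(0.2)


class TestBruteForceEquivalence:
    """The vectorized searches must agree with exhaustive scans."""

    def test_find_p1_matches_oracle(self, rng):
        for _ in range(120):
            v = random_test_signal(rng)
            fs = float(rng.uniform(50, 2000))
            a1 = float(rng.uniform(-0.5, 0.8))
            start = float(rng.uniform(0, 0.5)) * len(v) / fs
            expected = brute_force_p1(v, fs, 0.0, start, a1)
            if expected is None:
                with pytest.raises(ThresholdNeverCrossed):
                    find_p1(ts(v, fs), start, a1)
            else:
                assert find_p1(ts(v, fs), start, a1) == pytest.approx(expected, abs=1e-12)

    def test_next_local_max_matches_oracle(self, rng):
        for _ in range(120):
            v = random_test_signal(rng)
            fs = float(rng.uniform(50, 2000))
            start = float(rng.uniform(0, 0.7)) * len(v) / fs
            expected = brute_force_local_max(v, fs, 0.0, start)
            if expected is None:
                with pytest.raises(NoMaximumFound):
                    next_local_max(ts(v, fs), start)
            else:
                assert next_local_max(ts(v, fs), start) == pytest.approx(expected, abs=1e-12)


class TestDetectEvents:
    def two_bump_signal(self):
        t = np.arange(4501) / FS  # 3 s
        return ts(gauss(t, 1.0, 1.0, 0.1) + gauss(t, 1.6, 0.8, 0.08))

    def test_hand_built_two_bump_signal(self):
        x = self.two_bump_signal()
        params = AlgorithmParams(a1=0.3, a2=0.0, a3=0.0, a4=0.3, a5=0.0)
        det = detect_events(x, params, 0.2, filtered=False)
        assert abs(det.to_s - 1.0) <= 1.0 / FS + 1e-12
        assert abs(det.hs_s - 1.6) <= 1.0 / FS + 1e-12
        # P1 = rising 0.3-crossing of a unit Gaussian with sigma 0.1:
        # 1.0 - 0.1 * sqrt(2 ln(1/0.3))
        expected_p1 = 1.0 - 0.1 * np.sqrt(2 * np.log(1 / 0.3))
        assert abs(det.p1_s - expected_p1) <= 2.0 / FS
        assert det.hl_s == det.p1_s  # a2 = 0

    def test_advance_beyond_signal_fails(self):
        x = self.two_bump_signal()
        params = AlgorithmParams(a1=0.3, a2=0.0, a3=0.0, a4=10.0, a5=0.0)
        with pytest.raises(NoMaximumFound):
            detect_events(x, params, 0.2, filtered=False)

    def test_dc_offset_invariance(self, degenerate_trial):
        truth = degenerate_trial.truth
        params = _oracle_params(degenerate_trial)
        base = detect_events(degenerate_trial.sensor, params, truth.hs1_s)
        shifted_sensor = TimeSeries(
            degenerate_trial.sensor.values + 5.0, FS, degenerate_trial.sensor.t0_s
        )
        shifted = detect_events(shifted_sensor, params, truth.hs1_s)
        assert shifted == base

    def test_time_shift_equivariance(self, degenerate_trial):
        truth = degenerate_trial.truth
        params = _oracle_params(degenerate_trial)
        base = detect_events(degenerate_trial.sensor, params, truth.hs1_s)
        delta = 0.25
        shifted = detect_events(
            degenerate_trial.sensor.shifted(delta), params, truth.hs1_s + delta
        )
        for ev in ("hl_s", "to_s", "hs_s"):
            assert abs(getattr(shifted, ev) - getattr(base, ev) - delta) <= 1.0 / FS + 1e-9


def _oracle_params(trial):
    return calibrate([(trial, trial.truth)] * 2)


class TestCalibrate:
    def test_noiseless_self_consistency(self, degenerate_trials):
        """Calibrated on 5 identical clean trials, the detector reproduces truth."""
        training = [(t, t.truth) for t in degenerate_trials[:5]]
        params = calibrate(training)
        for trial, truth in training:
            det = detect_events(trial.sensor, params, truth.hs1_s)
            assert abs(det.hl_s - truth.hl_s) <= 1.0 / FS + 1e-9
            assert abs(det.to_s - truth.to_s) <= 1.0 / FS + 1e-9
            assert abs(det.hs_s - truth.hs2_s) <= 1.0 / FS + 1e-9

    def test_offsets_are_means_of_per_trial_offsets(self, degenerate_profile):
        jittered = dataclasses.replace(degenerate_profile, timing_jitter_sd_s=0.010)
        trials = [simulate_trial(jittered, s) for s in range(5)]
        training = [(t, t.truth) for t in trials]
        params, diag = calibrate_detailed(training)
        assert params.a2 == pytest.approx(np.mean(diag.a2_offsets), abs=1e-9)
        assert params.a3 == pytest.approx(np.mean(diag.a3_offsets), abs=1e-9)
        assert params.a4 == pytest.approx(0.5 * np.mean(diag.a4_intervals), abs=1e-9)
        assert params.a5 == pytest.approx(np.mean(diag.a5_offsets), abs=1e-9)
        # and the recorded offsets really are anchor-to-truth differences
        for (trial, truth), a3_off in zip(training, diag.a3_offsets):
            prepared = prepare_detection_signal(trial.sensor)
            to_peak = next_local_max(prepared, truth.hl_s)
            assert a3_off == pytest.approx(truth.to_s - to_peak, abs=1e-12)

    def test_spurious_peak_rivaling_toe_off_is_infeasible(self, degenerate_profile):
        bad = dataclasses.replace(
            degenerate_profile, spurious_peak=True, spurious_amplitude_frac=1.1
        )
        trials = [simulate_trial(bad, s) for s in range(5)]
        with pytest.raises(CalibrationInfeasible):
            calibrate([(t, t.truth) for t in trials])

    def test_too_few_trials_rejected(self, degenerate_trial):
        with pytest.raises(ValueError, match="at least 2"):
            calibrate([(degenerate_trial, degenerate_trial.truth)])


class TestGracefulDegradation:
    def test_error_grows_with_timing_jitter(self, degenerate_profile):
        """Mean |HL error| is monotone in the jitter SD (seed-averaged)."""
        from gaitsock.evaluate import evaluate_subject

        means = []
        for sd in (0.0, 0.005, 0.010, 0.020):
            p = dataclasses.replace(degenerate_profile, timing_jitter_sd_s=sd)
            errs = []
            for rep in range(3):
                trials = [simulate_trial(p, 100 * rep + s, trial_index=s) for s in range(10)]
                report = evaluate_subject(trials)
                errs.append(report.mean_abs_pct_gc["HL"])
            means.append(np.mean(errs))
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))
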