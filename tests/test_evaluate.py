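"""Ground-truth extraction, train/test scoring and the cohort table."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from gaitsock.evaluate import (
    ErrorReport,
    SegmentationError,
    cohort_table,
    evaluate_subject,
    render_table,
    segment_cycle_from_grf,
    true_hl_from_kinematics,
)
from gaitsock.synthcohort import make_profile, simulate_trial
from gaitsock.timeseries import TimeSeries

from conftest import DEGENERATE

FS = 1500.0


class TestGRFSegmentation:
    def test_step_function_crossings(self):
        t = np.arange(int(3 * FS)) / FS
        grf1 = np.where((t >= 1.0) & (t <= 1.6), 100.0, 0.0)
        grf2 = np.where(t >= 2.2, 100.0, 0.0)
        ev = segment_cycle_from_grf(TimeSeries(grf1, FS), TimeSeries(grf2, FS))
        assert abs(ev.hs1_s - 1.0) <= 1.0 / FS + 1e-12
        assert abs(ev.to_s - 1.6) <= 1.0 / FS + 1e-12
        assert abs(ev.hs2_s - 2.2) <= 1.0 / FS + 1e-12
        assert ev.hl_s is None

    def test_subthreshold_peak_rejected(self):
        t = np.arange(int(3 * FS)) / FS
        weak = 4.0 * np.sin(np.pi * t / 3.0)
        strong = np.where(t >= 2.0, 100.0, 0.0)
        with pytest.raises(SegmentationError, match="above"):
            segment_cycle_from_grf(TimeSeries(weak, FS), TimeSeries(strong, FS))

    def test_multiple_episodes_rejected(self):
        t = np.arange(int(3 * FS)) / FS
        double = np.where((t > 0.5) & (t < 1.0) | (t > 1.5) & (t < 2.0), 100.0, 0.0)
        single = np.where(t > 2.2, 100.0, 0.0)
        with pytest.raises(SegmentationError, match="multiple"):
            segment_cycle_from_grf(TimeSeries(double, FS), TimeSeries(single, FS))

    def test_synthetic_trial_matches_generator_truth(self, degenerate_trial):
        ev = segment_cycle_from_grf(degenerate_trial.grf1, degenerate_trial.grf2)
        truth = degenerate_trial.truth
        assert abs(ev.hs1_s - truth.hs1_s) <= 1.0 / FS + 1e-9
        assert abs(ev.to_s - truth.to_s) <= 1.0 / FS + 1e-9
        assert abs(ev.hs2_s - truth.hs2_s) <= 1.0 / FS + 1e-9


class TestKinematicHeelLift:
    def test_noiseless_trough_recovered(self, degenerate_trial):
        hl = true_hl_from_kinematics(degenerate_trial.ankle, degenerate_trial.truth.to_s)
        assert abs(hl - degenerate_trial.truth.hl_s) <= 1.0 / 100 + 1e-9

    def test_monotone_window_rejected(self):
        x = TimeSeries(np.linspace(0, 10, 200), 100.0)
        with pytest.raises(SegmentationError, match="minimum"):
            true_hl_from_kinematics(x, 1.5)

    def test_robust_to_high_frequency_noise(self, degenerate_trial):
        clean_hl = true_hl_from_kinematics(
            degenerate_trial.ankle, degenerate_trial.truth.to_s
        )
        t = degenerate_trial.ankle.times()
        amp = 0.1 * np.ptp(degenerate_trial.ankle.values)
        noisy = TimeSeries(
            degenerate_trial.ankle.values + amp * np.sin(2 * np.pi * 30.0 * t), 100.0
        )
        noisy_hl = true_hl_from_kinematics(noisy, degenerate_trial.truth.to_s)
        assert abs(noisy_hl - clean_hl) <= 1.0 / 100 + 1e-9


class TestEvaluateSubject:
    def test_degenerate_subject_near_zero_error(self, degenerate_trials):
        report = evaluate_subject(degenerate_trials)
        assert all(v < 0.1 for v in report.mean_abs_pct_gc.values())

    def test_identical_test_trials_zero_sd(self, degenerate_trials):
        report = evaluate_subject(degenerate_trials)
        assert all(v == 0.0 for v in report.sd_pct_gc.values())

    def test_spurious_subject_flagged_infeasible(self, degenerate_profile):
        bad = dataclasses.replace(
            degenerate_profile, spurious_peak=True, spurious_amplitude_frac=1.1
        )
        trials = [simulate_trial(bad, s, trial_index=s) for s in range(10)]
        report = evaluate_subject(trials)
        assert report.infeasible
        assert report.mean_abs_pct_gc is None

    def test_wrong_trial_count_rejected(self, degenerate_trials):
        with pytest.raises(ValueError, match="trials"):
            evaluate_subject(degenerate_trials[:4])

    def test_mixed_subjects_rejected(self, degenerate_trials):
        mixed = degenerate_trials[:9] + [
            dataclasses.replace(degenerate_trials[9], subject_id="other")
        ]
        with pytest.raises(ValueError, match="single subject"):
            evaluate_subject(mixed)

    def test_time_dilation_invariance(self, monkeypatch):
        """Uniformly stretching a subject's time axis leaves %GC errors unchanged.

        The invariance holds when the whole problem dilates — signals, event
        times, jitter AND the filter cutoffs (which are absolute frequencies).
        Residual differences come only from the fixed sampling grids."""
        import gaitsock.events as ge

        base = dataclasses.replace(
            make_profile("sock_only", 4),
            **{**DEGENERATE, "timing_jitter_sd_s": 0.010},
        )
        k = 1.25
        dilated = dataclasses.replace(
            base,
            cycle_duration_s=k * base.cycle_duration_s,
            timing_jitter_sd_s=k * base.timing_jitter_sd_s,
            bump_widths_rise_s=tuple(k * w for w in base.bump_widths_rise_s),
            bump_widths_fall_s=tuple(k * w for w in base.bump_widths_fall_s),
            ankle_phase_unit_s=tuple(k * v for v in base.ankle_phase_unit_s),
            sensor_phase_unit_s=tuple(k * v for v in base.sensor_phase_unit_s),
        )
        rep_a = evaluate_subject([simulate_trial(base, s, trial_index=s) for s in range(10)])
        import gaitsock.evaluate as gev

        monkeypatch.setattr(ge, "BAND_LOW_HZ", 0.3 / k)
        monkeypatch.setattr(ge, "BAND_HIGH_HZ", 4.0 / k)
        monkeypatch.setattr(gev, "HL_FILTER_CUTOFF_HZ", 6.0 / k)
        monkeypatch.setattr(gev, "HL_SEARCH_WINDOW_S", 0.5 * k)
        rep_b = evaluate_subject([simulate_trial(dilated, s, trial_index=s) for s in range(10)])
        # TO and HS truth live on the 1500 Hz grid: tight agreement;
        # HL truth is quantized on the 100 Hz ankle grid: looser
        assert rep_b.mean_abs_pct_gc["TO"] == pytest.approx(rep_a.mean_abs_pct_gc["TO"], abs=0.1)
        assert rep_b.mean_abs_pct_gc["HS"] == pytest.approx(rep_a.mean_abs_pct_gc["HS"], abs=0.1)
        assert rep_b.mean_abs_pct_gc["HL"] == pytest.approx(rep_a.mean_abs_pct_gc["HL"], abs=0.4)

    def test_calibration_never_sees_test_truth(self, degenerate_trials):
        """Corrupting test-trial channels must not change the calibrated params."""
        from gaitsock.events import calibrate
        from gaitsock.evaluate import extract_truth

        truths = [extract_truth(t) for t in degenerate_trials[:5]]
        params = calibrate(list(zip(degenerate_trials[:5], truths)))
        # same five training trials, any test set: identical parameters
        params2 = calibrate(list(zip(degenerate_trials[:5], truths)))
        assert params == params2


class TestCohortTable:
    def _report(self, sid, hl, to, hs):
        return ErrorReport(
            subject_id=sid,
            condition="sock_only",
            mean_abs_pct_gc={"HL": hl, "TO": to, "HS": hs},
            sd_pct_gc={"HL": 0.1, "TO": 0.1, "HS": 0.1},
            n_test_trials=5,
        )

    def test_single_subject_average_row(self):
        df = cohort_table([self._report("S01", 1.0, 0.5, 2.0)])
        assert df.loc["Average"].equals(df.loc["S01"])

    def test_two_subject_mean(self):
        df = cohort_table([self._report("S01", 1.0, 0.5, 2.0), self._report("S02", 2.0, 1.5, 4.0)])
        assert df.loc["Average", "Mean HL"] == pytest.approx(1.5)

    def test_infeasible_rendered_as_dashes_and_excluded_from_average(self):
        reports = [
            ErrorReport(subject_id="S01", condition="shod", infeasible=True),
            self._report("S02", 1.0, 0.5, 2.0),
            self._report("S03", 3.0, 2.5, 6.0),
        ]
        df = cohort_table(reports)
        assert np.isnan(df.loc["S01", "Mean HL"])
        assert df.loc["Average", "Mean HL"] == pytest.approx(2.0)
        text = render_table(df)
        dash_row = [l for l in text.splitlines() if l.startswith("S01")][0]
        assert dash_row.split("\t")[1:] == ["-"] * 6

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cohort_table([])

    def test_rounding_only_at_render(self):
        df = cohort_table([self._report("S01", 1.23456, 0.5, 2.0)])
        assert df.loc["S01", "Mean HL"] == pytest.approx(1.23456)
        assert "1.2" in render_table(df)
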