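"""Ground-truth extraction and train/test evaluation in % gait cycle.

Truth comes from the laboratory reference channels, never from the sensor:
the two force platforms give the heel strikes and toe off via the 5 N
vertical-GRF threshold, and heel lift is the minimum of the 6 Hz low-passed
ankle angle just before toe off (the onset of pre-swing plantarflexion).

Per subject/condition, the detector is calibrated on the first five trials
and scored on the last five; errors are expressed in % gait cycle of each
test trial's own cycle duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .events import CalibrationInfeasible, GaitEventError, calibrate, detect_events
from .records import GRF_THRESHOLD_N, EventTimes, TrialRecord
from .sigproc import butter_lowpass_zero_lag
from .timeseries import TimeSeries

__all__ = [
    "ErrorReport",
    "SegmentationError",
    "segment_cycle_from_grf",
    "true_hl_from_kinematics",
    "extract_truth",
    "evaluate_subject",
    "cohort_table",
    "render_table",
]

EVENTS = ("HL", "TO", "HS")
HL_SEARCH_WINDOW_S = 0.5
HL_FILTER_CUTOFF_HZ = 6.0
HL_FILTER_ORDER = 4
N_TRAIN_DEFAULT = 5


class SegmentationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ErrorReport:
    """Per-subject detector accuracy: mean |error| and SD of signed error (%GC)."""

    subject_id: str
    condition: str
    infeasible: bool = False
    mean_abs_pct_gc: Optional[Dict[str, float]] = None
    sd_pct_gc: Optional[Dict[str, float]] = None
    signed_errors_pct_gc: Optional[Dict[str, Tuple[float, ...]]] = None
    n_test_trials: int = 0

    def __post_init__(self) -> None:
        if self.infeasible:
            if self.mean_abs_pct_gc is not None or self.sd_pct_gc is not None:
                raise ValueError("infeasible report must not carry error fields")
        else:
            if self.mean_abs_pct_gc is None or self.sd_pct_gc is None:
                raise ValueError("feasible report requires error fields")
            for d in (self.mean_abs_pct_gc, self.sd_pct_gc):
                if set(d) != set(EVENTS):
                    raise ValueError(f"error fields must cover {EVENTS}")
                if any(v < 0 for v in d.values()):
                    raise ValueError("error magnitudes must be non-negative")


def _threshold_episode(g: TimeSeries, label: str) -> Tuple[int, int]:
    """First/last index of the single contiguous supra-5 N episode."""
    above = g.values > GRF_THRESHOLD_N
    idx = np.flatnonzero(above)
    if idx.size == 0:
        raise SegmentationError(f"{label}: no samples above {GRF_THRESHOLD_N} N")
    # contiguity check: one rising edge only
    edges = np.flatnonzero(np.diff(above.astype(int)) == 1).size + int(above[0])
    if edges > 1:
        raise SegmentationError(f"{label}: multiple supra-threshold episodes")
    return int(idx[0]), int(idx[-1])


def segment_cycle_from_grf(grf1: TimeSeries, grf2: TimeSeries) -> EventTimes:
    """Gait-cycle boundaries from the force platforms.

    HS1 = first grf1 sample above 5 N; TO = last grf1 sample above 5 N;
    HS2 = first grf2 sample above 5 N.  "Exceeded" is read strictly.
    Heel lift is not derivable from GRF and is left absent.
    """
    i_hs1, i_to = _threshold_episode(grf1, "grf1")
    i_hs2, _ = _threshold_episode(grf2, "grf2")
    return EventTimes(
        hs1_s=grf1.time_at(i_hs1), to_s=grf1.time_at(i_to), hs2_s=grf2.time_at(i_hs2)
    )


def true_hl_from_kinematics(ankle: TimeSeries, to_s: float) -> float:
    """Heel lift: last local minimum of the 6 Hz low-passed ankle angle before toe off.

    The search window is [to_s - 0.5 s, to_s), covering terminal stance at
    normal cadence.
    """
    if not ankle.t0_s <= to_s <= ankle.t_end_s:
        raise ValueError("toe-off time outside the ankle signal")
    if to_s - ankle.t0_s < 0.3:
        raise ValueError("need at least 0.3 s of ankle signal before toe off")
    smooth = butter_lowpass_zero_lag(ankle, HL_FILTER_CUTOFF_HZ, HL_FILTER_ORDER)
    i_to = smooth.index_at(to_s, clip=True)
    i_lo = max(smooth.index_at(to_s - HL_SEARCH_WINDOW_S, clip=True), 1)
    v = smooth.values
    mins = [
        i
        for i in range(i_lo, min(i_to, len(v) - 1))
        if v[i - 1] > v[i] <= v[i + 1]
    ]
    if not mins:
        raise SegmentationError("no kinematic minimum before toe off in the search window")
    return smooth.time_at(mins[-1])


def extract_truth(trial: TrialRecord) -> EventTimes:
    """Full reference event times from the GRF and kinematic channels."""
    grf_events = segment_cycle_from_grf(trial.grf1, trial.grf2)
    hl = true_hl_from_kinematics(trial.ankle, grf_events.to_s)
    return EventTimes(
        hs1_s=grf_events.hs1_s, hl_s=hl, to_s=grf_events.to_s, hs2_s=grf_events.hs2_s
    )


def evaluate_subject(
    trials: Sequence[TrialRecord],
    n_train: int = N_TRAIN_DEFAULT,
    filtered: bool = True,
) -> ErrorReport:
    """Calibrate on the first ``n_train`` trials, score on the remainder.

    Truth is re-derived from the reference channels for every trial; the
    calibration never sees a test trial.  Per test trial and event,
    error% = 100 * (t_true - t_pred) / cycle duration; reported are the mean
    of |error%| and the sample SD of the signed error% across test trials.
    A subject whose training trials admit no workable threshold is flagged
    infeasible instead of carrying numbers.
    """
    if len(trials) <= n_train:
        raise ValueError(f"need more than {n_train} trials (got {len(trials)})")
    subject_ids = {t.subject_id for t in trials}
    conditions = {t.condition for t in trials}
    if len(subject_ids) != 1 or len(conditions) != 1:
        raise ValueError("trials must come from a single subject and condition")
    sid, cond = subject_ids.pop(), conditions.pop()

    truths = [extract_truth(t) for t in trials]
    try:
        params = calibrate(list(zip(trials[:n_train], truths[:n_train])), filtered=filtered)
    except CalibrationInfeasible:
        return ErrorReport(subject_id=sid, condition=cond, infeasible=True)

    signed: Dict[str, List[float]] = {e: [] for e in EVENTS}
    for trial, truth in zip(trials[n_train:], truths[n_train:]):
        try:
            det = detect_events(trial.sensor, params, truth.hs1_s, filtered=filtered)
        except GaitEventError:
            # calibrated threshold unusable on a held-out trial: the detector
            # cannot serve this subject, same verdict as failed calibration
            return ErrorReport(subject_id=sid, condition=cond, infeasible=True)
        cyc = truth.cycle_duration_s
        signed["HL"].append(100.0 * (truth.hl_s - det.hl_s) / cyc)
        signed["TO"].append(100.0 * (truth.to_s - det.to_s) / cyc)
        signed["HS"].append(100.0 * (truth.hs2_s - det.hs_s) / cyc)

    n_test = len(trials) - n_train
    return ErrorReport(
        subject_id=sid,
        condition=cond,
        mean_abs_pct_gc={e: float(np.mean(np.abs(signed[e]))) for e in EVENTS},
        sd_pct_gc={
            e: float(np.std(signed[e], ddof=1)) if n_test > 1 else 0.0 for e in EVENTS
        },
        signed_errors_pct_gc={e: tuple(signed[e]) for e in EVENTS},
        n_test_trials=n_test,
    )


def cohort_table(reports: Sequence[ErrorReport]) -> pd.DataFrame:
    """Per-subject accuracy table with an Average row.

    Columns: Mean/Std per event in %GC.  Infeasible subjects carry NaN and
    are excluded from the Average; full precision is kept — rounding to one
    decimal happens only in :func:`render_table`.
    """
    if not reports:
        raise ValueError("no reports supplied")
    cols = ["Mean HL", "Std HL", "Mean TO", "Std TO", "Mean HS", "Std HS"]
    rows = {}
    for rep in reports:
        if rep.infeasible:
            rows[rep.subject_id] = [np.nan] * 6
        else:
            rows[rep.subject_id] = [
                rep.mean_abs_pct_gc["HL"], rep.sd_pct_gc["HL"],
                rep.mean_abs_pct_gc["TO"], rep.sd_pct_gc["TO"],
                rep.mean_abs_pct_gc["HS"], rep.sd_pct_gc["HS"],
            ]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.loc["Average"] = df.mean(axis=0, skipna=True)
    df.index.name = "Subject"
    return df


def render_table(df: pd.DataFrame) -> str:
    """Delimited-text rendering, one decimal, infeasible rows as dashes."""
    out = df.round(1).astype(object)
    out = out.where(~df.isna(), "-")
    return out.to_csv(sep="\t")
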