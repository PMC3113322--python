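"""Peak-plus-offset gait event detection and its per-subject calibration.

The detector exploits two repeatable features of the sock voltage: the rapid
rise to a maximum around toe off (driven by the fast plantarflexion of
pre-swing) and a second maximum at the end of the cycle around the next heel
strike.  Three stages, five parameters:

1. forward-search from the first heel strike for the first point P1 where the
   prepared signal is rising and exceeds a voltage threshold a1; heel lift is
   P1 + a2;
2. the first local maximum after P1 is the toe-off peak; toe off is that
   maximum + a3;
3. advance by a4 (to skip the mid-swing trough), find the next local maximum
   (the heel-strike peak); heel strike is that maximum + a5.

a1 is in volts on the detection signal; a2, a3, a5 are signed offsets and a4 a
strictly positive advance, all in seconds (not % cycle) so the detector works
on a raw voltage stream without knowing the cadence.  The offsets are
typically negative: the sensor features trail the physical events, which is
why the method is retrospective rather than real-time.

Calibration estimates all five from a handful of training trials with known
event times, and fails explicitly (``CalibrationInfeasible``) when no
threshold separates the toe-off rise from earlier peaks — the documented
failure mode of shod walking, where a spurious peak near 30% gait cycle can
rival the toe-off peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .records import EventTimes, TrialRecord
from .sigproc import fft_bandpass
from .timeseries import TimeSeries

__all__ = [
    "AlgorithmParams",
    "DetectionResult",
    "CalibrationDiagnostics",
    "GaitEventError",
    "ThresholdNeverCrossed",
    "NoMaximumFound",
    "PredictionOutsideSignal",
    "CalibrationInfeasible",
    "prepare_detection_signal",
    "find_p1",
    "next_local_max",
    "detect_events",
    "calibrate",
    "calibrate_detailed",
]

BAND_LOW_HZ = 0.3
BAND_HIGH_HZ = 4.0

# calibration constants: heel-strike peak search window (fraction of the cycle
# around the true second heel strike) and the threshold-lowering fallback
HS_PEAK_WINDOW_FRAC = 0.25
A1_LOWER_FACTOR = 0.9
A1_MAX_LOWERINGS = 5


class GaitEventError(RuntimeError):
    """Base class for detector failures; the stage name is in the message."""


class ThresholdNeverCrossed(GaitEventError):
    pass


class NoMaximumFound(GaitEventError):
    pass


class PredictionOutsideSignal(GaitEventError):
    pass


class CalibrationInfeasible(GaitEventError):
    pass


@dataclass(frozen=True)
class AlgorithmParams:
    """The five detector parameters: a1 (V) and a2-a5 (s)."""

    a1: float
    a2: float
    a3: float
    a4: float
    a5: float

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "a3", "a4", "a5"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not self.a4 > 0:
            raise ValueError("a4 (advance time) must be > 0")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("a1", "a2", "a3", "a4", "a5")}


@dataclass(frozen=True)
class DetectionResult:
    """Predicted event times plus the anchor features they were offset from."""

    hl_s: float
    to_s: float
    hs_s: float
    p1_s: float
    to_peak_s: float
    hs_peak_s: float


def prepare_detection_signal(sensor: TimeSeries, filtered: bool = True) -> TimeSeries:
    """Detection signal: the 0.3-4 Hz band-passed sensor voltage.

    The high-pass edge removes baseline drift of the knitted sensor, the 4 Hz
    low-pass edge suppresses measurement noise while keeping the gait
    waveform.  No amplitude scaling — the threshold a1 stays in volts.
    With ``filtered=False`` the raw voltage is passed through unchanged.
    """
    if not filtered:
        return sensor
    return fft_bandpass(sensor, BAND_LOW_HZ, BAND_HIGH_HZ)


def find_p1(x: TimeSeries, start_s: float, a1: float) -> float:
    """Time of the first sample at/after ``start_s`` that is rising and exceeds a1.

    Rising means strictly greater than the previous sample.
    """
    i0 = max(int(np.ceil((start_s - x.t0_s) * x.fs_hz - 1e-9)), 1)
    if i0 >= len(x):
        raise ThresholdNeverCrossed("threshold-never-crossed: search start at end of signal")
    v = x.values
    above = v[i0:] > a1
    rising = v[i0:] > v[i0 - 1 : -1]
    hits = np.flatnonzero(above & rising)
    if hits.size == 0:
        raise ThresholdNeverCrossed(
            f"threshold-never-crossed: no rising sample above a1={a1:.4g} after {start_s:.4g} s"
        )
    return x.time_at(i0 + int(hits[0]))


def next_local_max(x: TimeSeries, from_s: float) -> float:
    """Time of the first local maximum at/after ``from_s``.

    A sample i is a local maximum when x[i-1] < x[i] >= x[i+1]; a plateau
    resolves to its first sample and the signal endpoints never qualify.
    """
    i0 = max(int(np.ceil((from_s - x.t0_s) * x.fs_hz - 1e-9)), 1)
    v = x.values
    if i0 > len(x) - 2:
        raise NoMaximumFound("no-maximum-found: search start beyond last interior sample")
    seg = v[i0 : len(v) - 1]
    hits = np.flatnonzero((seg > v[i0 - 1 : len(v) - 2]) & (seg >= v[i0 + 1 :]))
    if hits.size == 0:
        raise NoMaximumFound(f"no-maximum-found: no interior maximum after {from_s:.4g} s")
    return x.time_at(i0 + int(hits[0]))


def detect_events(
    sensor: TimeSeries,
    params: AlgorithmParams,
    search_start_s: float,
    filtered: bool = True,
) -> DetectionResult:
    """Run the 3-stage forward search from the first heel strike.

    ``search_start_s`` is the time of the first heel strike (t = 0 of the
    cycle).  ``filtered`` selects whether detection runs on the band-passed
    (default) or raw voltage.
    """
    x = prepare_detection_signal(sensor, filtered=filtered)
    p1 = find_p1(x, search_start_s, params.a1)
    hl = p1 + params.a2
    to_peak = next_local_max(x, p1)
    to = to_peak + params.a3
    hs_peak = next_local_max(x, to_peak + params.a4)
    hs = hs_peak + params.a5
    for name, t in (("HL", hl), ("TO", to), ("HS", hs)):
        if not x.t0_s <= t <= x.t_end_s:
            raise PredictionOutsideSignal(
                f"prediction-outside-signal: {name} predicted at {t:.4g} s"
            )
    return DetectionResult(hl_s=hl, to_s=to, hs_s=hs, p1_s=p1, to_peak_s=to_peak, hs_peak_s=hs_peak)


@dataclass(frozen=True)
class CalibrationDiagnostics:
    """Per-trial anchor offsets behind the calibrated means.

    The spread of each offset across training trials is the natural
    uncertainty of the corresponding parameter.
    """

    a1_candidates: Tuple[float, ...]
    a2_offsets: Tuple[float, ...]
    a3_offsets: Tuple[float, ...]
    a4_intervals: Tuple[float, ...]
    a5_offsets: Tuple[float, ...]
    n_lowerings: int

    def offset_sd(self) -> dict:
        """Sample SD (s) of the per-trial offsets behind a2-a5 (NaN for n=1)."""
        def sd(v):
            return float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")

        return {
            "a2": sd(self.a2_offsets),
            "a3": sd(self.a3_offsets),
            "a4": sd(np.asarray(self.a4_intervals) * 0.5),
            "a5": sd(self.a5_offsets),
        }


def _anchor_features(
    prepared: TimeSeries, truth: EventTimes
) -> Tuple[float, float, float, float]:
    """Locate the toe-off and heel-strike peaks of one training trial.

    Returns (to_peak, hs_peak, early_max_v, to_peak_v): the two anchor times,
    the maximum of the prepared signal over the initial stage [HS1, HL] (which
    any workable threshold must exceed) and the voltage at the toe-off peak
    (which it must stay below).
    """
    if truth.hl_s is None:
        raise ValueError("calibration requires trials with heel-lift truth")
    to_peak = next_local_max(prepared, truth.hl_s)
    cycle = truth.cycle_duration_s
    win_lo = truth.hs2_s - HS_PEAK_WINDOW_FRAC * cycle
    hs_peak = next_local_max(prepared, win_lo)
    if hs_peak > truth.hs2_s + HS_PEAK_WINDOW_FRAC * cycle:
        raise CalibrationInfeasible(
            "calibration-infeasible: no heel-strike peak within the search window"
        )
    if not hs_peak > to_peak:
        raise CalibrationInfeasible(
            "calibration-infeasible: toe-off and heel-strike peaks not ordered"
        )
    early = prepared.slice_time(truth.hs1_s, truth.hl_s, half_open=False)
    early_max_v = float(np.max(early.values))
    to_peak_v = float(prepared.values[prepared.index_at(to_peak)])
    return to_peak, hs_peak, early_max_v, to_peak_v


def calibrate_detailed(
    training: Sequence[Tuple[TrialRecord, EventTimes]],
    filtered: bool = True,
) -> Tuple[AlgorithmParams, CalibrationDiagnostics]:
    """Estimate a1-a5 from training trials with known event times.

    Per trial the toe-off peak (first local maximum after true heel lift) and
    heel-strike peak (first local maximum within +/-25% cycle of the true
    second heel strike) are located on the prepared signal.  The threshold a1
    is set midway between the largest early-stance value (over [HS1, HL] —
    the region the forward search must NOT trigger in) and the toe-off peak
    voltage, averaged over trials.  The choice is then verified: P1 found with
    a1 must land on the rising edge of the toe-off peak in every training
    trial; if not, a1 is lowered in 10% steps (at most 5) before declaring
    calibration infeasible.  a2, a3, a5 are the mean anchor-to-event offsets
    and a4 is half the mean toe-off-peak-to-heel-strike-peak interval, which
    skips the mid-swing trough with maximal margin.
    """
    if len(training) < 2:
        raise ValueError("calibration needs at least 2 training trials")
    prepared = [prepare_detection_signal(tr.sensor, filtered=filtered) for tr, _ in training]
    truths = [ev for _, ev in training]

    anchors = [_anchor_features(x, ev) for x, ev in zip(prepared, truths)]
    to_peaks = [a[0] for a in anchors]
    hs_peaks = [a[1] for a in anchors]
    a1_candidates = [lo + 0.5 * (hi - lo) for _, _, lo, hi in anchors]
    a1 = float(np.mean(a1_candidates))

    n_lowerings = 0
    p1s: Optional[List[float]] = None
    for attempt in range(A1_MAX_LOWERINGS + 1):
        ok = True
        trial_p1s: List[float] = []
        for x, ev, to_pk in zip(prepared, truths, to_peaks):
            try:
                p1 = find_p1(x, ev.hs1_s, a1)
                on_edge = (p1 <= to_pk + 1e-12) and (
                    abs(next_local_max(x, p1) - to_pk) < 0.5 / x.fs_hz
                )
            except GaitEventError:
                on_edge = False
                p1 = np.nan
            if not on_edge:
                ok = False
                break
            trial_p1s.append(p1)
        if ok:
            p1s = trial_p1s
            break
        a1 *= A1_LOWER_FACTOR
        n_lowerings = attempt + 1
    if p1s is None:
        raise CalibrationInfeasible(
            "calibration-infeasible: no threshold isolates the toe-off rise "
            "in every training trial"
        )

    a2_off = [ev.hl_s - p1 for ev, p1 in zip(truths, p1s)]
    a3_off = [ev.to_s - tp for ev, tp in zip(truths, to_peaks)]
    a4_int = [hp - tp for hp, tp in zip(hs_peaks, to_peaks)]
    a5_off = [ev.hs2_s - hp for ev, hp in zip(truths, hs_peaks)]
    params = AlgorithmParams(
        a1=a1,
        a2=float(np.mean(a2_off)),
        a3=float(np.mean(a3_off)),
        a4=0.5 * float(np.mean(a4_int)),
        a5=float(np.mean(a5_off)),
    )
    diag = CalibrationDiagnostics(
        a1_candidates=tuple(a1_candidates),
        a2_offsets=tuple(a2_off),
        a3_offsets=tuple(a3_off),
        a4_intervals=tuple(a4_int),
        a5_offsets=tuple(a5_off),
        n_lowerings=n_lowerings,
    )
    return params, diag


def calibrate(
    training: Sequence[Tuple[TrialRecord, EventTimes]], filtered: bool = True
) -> AlgorithmParams:
    """As :func:`calibrate_detailed`, returning only the parameters."""
    return calibrate_detailed(training, filtered=filtered)[0]
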