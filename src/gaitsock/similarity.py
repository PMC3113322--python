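"""Sensor-vs-kinematic signal agreement per gait cycle.

Two per-cycle statistics quantify how well the sock voltage tracks the
sagittal ankle angle: Pearson's r and the normalised mean absolute deviation
(nMAD) between the two curves after each has been multiplicatively scaled to
unit peak-to-peak range.  Per-subject values are arithmetic means over the
available cycles (one per walking trial).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy import stats as spstats

from .records import EventTimes, TrialRecord, SENSOR_FS_HZ
from .sigproc import fft_bandpass, resample_linear
from .timeseries import TimeSeries

__all__ = ["SimilarityResult", "pearson_r", "nmad", "compare_cycle", "subject_similarity"]

BAND_LOW_HZ = 0.3
BAND_HIGH_HZ = 4.0


@dataclass(frozen=True)
class SimilarityResult:
    r: float
    nmad: float
    n_samples: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("r outside [-1, 1]")
        if self.nmad < 0:
            raise ValueError("nmad must be non-negative")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


def _check_pair(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    return a, b


def pearson_r(a: Sequence[float], b: Sequence[float]) -> float:
    """Product-moment correlation between two equal-length vectors."""
    a, b = _check_pair(a, b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(spstats.pearsonr(a, b).statistic)


def nmad(a: Sequence[float], b: Sequence[float]) -> float:
    """Mean absolute deviation after scaling each vector to unit peak-to-peak range.

    Scaling is multiplicative only (no offset alignment), so the statistic is
    invariant to positive rescaling of either argument but not to shifts —
    shifts are removed upstream by the band-pass.
    """
    a, b = _check_pair(a, b)
    pa, pb = np.ptp(a), np.ptp(b)
    if pa == 0 or pb == 0:
        raise ValueError("nmad undefined for a constant input")
    return float(np.mean(np.abs(a / pa - b / pb)))


def compare_cycle(trial: TrialRecord, cycle: EventTimes) -> SimilarityResult:
    """Similarity statistics for one gait cycle of one trial.

    Pipeline: slice sensor and ankle channels to [HS1, HS2) (half-open at the
    sensor grid so HS2 is not double counted), upsample the ankle channel to
    1500 Hz, band-pass both at 0.3-4 Hz, then compute r and nMAD on the
    overlapping samples.
    """
    if not (trial.sensor.t0_s <= cycle.hs1_s < cycle.hs2_s <= trial.sensor.t_end_s):
        raise ValueError("cycle outside the trial span")
    sens = trial.sensor.slice_time(cycle.hs1_s, cycle.hs2_s, half_open=True)
    ankle = resample_linear(trial.ankle, SENSOR_FS_HZ)
    ank = ankle.slice_time(cycle.hs1_s, cycle.hs2_s, half_open=True)
    # trim to a common length: upsampling can differ by one edge sample
    n = min(len(sens), len(ank))
    sv = fft_bandpass(_trim(sens, n), BAND_LOW_HZ, BAND_HIGH_HZ).values
    av = fft_bandpass(_trim(ank, n), BAND_LOW_HZ, BAND_HIGH_HZ).values
    return SimilarityResult(r=pearson_r(sv, av), nmad=nmad(sv, av), n_samples=n)


def _trim(x: "TimeSeries", n: int) -> "TimeSeries":
    return TimeSeries(x.values[:n], x.fs_hz, x.t0_s)


def subject_similarity(
    cycles: Iterable[Tuple[TrialRecord, EventTimes]]
) -> SimilarityResult:
    """Mean r and nMAD over a subject's gait cycles (one per trial)."""
    results = [compare_cycle(trial, cyc) for trial, cyc in cycles]
    if not results:
        raise ValueError("no cycles supplied")
    return SimilarityResult(
        r=float(np.mean([s.r for s in results])),
        nmad=float(np.mean([s.nmad for s in results])),
        n_samples=min(s.n_samples for s in results),
    )
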