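"""Core record types shared across the package: gait events and walking trials."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .timeseries import TimeSeries

SENSOR_FS_HZ = 1500.0
ANKLE_FS_HZ = 100.0
GRF_THRESHOLD_N = 5.0


@dataclass(frozen=True)
class EventTimes:
    """Absolute times (s) of the gait events bounding one cycle.

    hs1 and hs2 are consecutive heel strikes of opposite feet (from the two
    force platforms), hl the heel lift and to the toe off of the instrumented
    side.  A partial record (hl absent) is produced by GRF-only segmentation.
    """

    hs1_s: float
    to_s: float
    hs2_s: float
    hl_s: Optional[float] = None

    def __post_init__(self) -> None:
        seq = [self.hs1_s]
        if self.hl_s is not None:
            seq.append(self.hl_s)
        seq += [self.to_s, self.hs2_s]
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"event times must be strictly increasing, got {seq}")

    @property
    def cycle_duration_s(self) -> float:
        return self.hs2_s - self.hs1_s


@dataclass(frozen=True)
class TrialRecord:
    """One walking trial: four synchronized channels plus metadata.

    sensor (V) and the two force-platform channels (N) are sampled at 1500 Hz,
    the ankle angle (deg) at 100 Hz; all share the same start time.  ``truth``
    is present only for synthetic trials (construction-time event times); real
    recordings carry None and downstream evaluation derives truth from the
    GRF and kinematic channels.
    """

    sensor: TimeSeries
    ankle: TimeSeries
    grf1: TimeSeries
    grf2: TimeSeries
    subject_id: str
    condition: str
    trial_index: int
    truth: Optional[EventTimes] = None

    def __post_init__(self) -> None:
        for name, ch, fs in (
            ("sensor", self.sensor, SENSOR_FS_HZ),
            ("ankle", self.ankle, ANKLE_FS_HZ),
            ("grf1", self.grf1, SENSOR_FS_HZ),
            ("grf2", self.grf2, SENSOR_FS_HZ),
        ):
            if abs(ch.fs_hz - fs) > 1e-6:
                raise ValueError(f"{name} channel must be sampled at {fs} Hz")
            if abs(ch.t0_s - self.sensor.t0_s) > 1e-12:
                raise ValueError("all channels must share the start time")
        if abs(self.sensor.duration_s - self.ankle.duration_s) > 1.0 / ANKLE_FS_HZ + 1e-9:
            raise ValueError("sensor and ankle spans differ by more than one ankle sample")
        if self.truth is not None:
            for t in (self.truth.hs1_s, self.truth.hl_s, self.truth.to_s, self.truth.hs2_s):
                if t is not None and not (self.sensor.t0_s <= t <= self.sensor.t_end_s):
                    raise ValueError("truth event outside the trial span")
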