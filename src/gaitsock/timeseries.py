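"""Uniformly sampled time series — the substrate of all signal math in the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued channel.

    Parameters
    ----------
    values : array-like
        Sample values, at least 2 of them.
    fs_hz : float
        Sampling frequency in Hz, strictly positive.
    t0_s : float
        Time of the first sample in seconds (default 0).
    """

    values: np.ndarray
    fs_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if vals.size < 2:
            raise ValueError("TimeSeries needs at least 2 samples")
        if not self.fs_hz > 0:
            raise ValueError("sampling frequency must be positive")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt_s(self) -> float:
        return 1.0 / self.fs_hz

    @property
    def duration_s(self) -> float:
        """Span from the first to the last sample."""
        return (len(self) - 1) / self.fs_hz

    @property
    def t_end_s(self) -> float:
        return self.t0_s + self.duration_s

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self)) / self.fs_hz

    def index_at(self, t_s: float, clip: bool = False) -> int:
        """Index of the sample nearest to time ``t_s``."""
        i = int(round((t_s - self.t0_s) * self.fs_hz))
        if clip:
            return min(max(i, 0), len(self) - 1)
        if not 0 <= i < len(self):
            raise IndexError(f"time {t_s} s outside series [{self.t0_s}, {self.t_end_s}] s")
        return i

    def time_at(self, i: int) -> float:
        return self.t0_s + i / self.fs_hz

    def slice_time(self, start_s: float, stop_s: float, half_open: bool = True) -> "TimeSeries":
        """Sub-series covering [start_s, stop_s) (or closed when half_open=False)."""
        i0 = int(np.ceil((start_s - self.t0_s) * self.fs_hz - 1e-9))
        i1 = int(np.floor((stop_s - self.t0_s) * self.fs_hz + 1e-9))
        if half_open and self.time_at(i1) >= stop_s - 1e-12:
            i1 -= 1
        i0 = max(i0, 0)
        i1 = min(i1, len(self) - 1)
        if i1 - i0 + 1 < 2:
            raise ValueError("requested slice contains fewer than 2 samples")
        return TimeSeries(self.values[i0 : i1 + 1], self.fs_hz, self.time_at(i0))

    def shifted(self, dt_s: float) -> "TimeSeries":
        return TimeSeries(self.values, self.fs_hz, self.t0_s + dt_s)
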