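"""Signal-conditioning primitives for the sock sensor pipeline.

The sensor voltage carries a slow baseline drift (a property of the knitted
piezo-resistive structure) on top of the gait waveform, and the optical ankle
kinematics are sampled 15x slower than the sensor.  Conditioning therefore
consists of four small operations: a zero-phase FFT (brick-wall) high-/band-pass
to remove drift while keeping the low-frequency content of walking, a zero-lag
Butterworth low-pass for kinematic noise, linear upsampling onto the sensor
grid, and multiplicative peak-to-peak matching between channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from .timeseries import TimeSeries

__all__ = [
    "FilterSpec",
    "fft_filter",
    "fft_highpass",
    "fft_bandpass",
    "butter_lowpass_zero_lag",
    "resample_linear",
    "scale_peak_to_peak",
]


@dataclass(frozen=True)
class FilterSpec:
    """Declarative filter description.

    kind is one of ``fft_highpass``, ``fft_bandpass``, ``butter_lowpass``.
    Cutoffs are validated against the sampling rate at application time.
    """

    kind: str
    low_cut_hz: Optional[float] = None
    high_cut_hz: Optional[float] = None
    order: int = 4
    zero_lag: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("fft_highpass", "fft_bandpass", "butter_lowpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind == "fft_highpass" and self.low_cut_hz is None:
            raise ValueError("fft_highpass requires low_cut_hz")
        if self.kind == "fft_bandpass":
            if self.low_cut_hz is None or self.high_cut_hz is None:
                raise ValueError("fft_bandpass requires both cutoffs")
            if not self.low_cut_hz < self.high_cut_hz:
                raise ValueError("band-pass requires low_cut < high_cut")
        if self.kind == "butter_lowpass" and self.high_cut_hz is None:
            raise ValueError("butter_lowpass requires high_cut_hz")
        for c in (self.low_cut_hz, self.high_cut_hz):
            if c is not None and not c > 0:
                raise ValueError("cutoff frequencies must be positive")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


def fft_filter(x: TimeSeries, spec: FilterSpec) -> TimeSeries:
    """Zero-phase brick-wall filter in the frequency domain.

    The discrete Fourier transform of the signal is computed, every bin whose
    frequency magnitude lies outside the pass band is zeroed (band edges
    inclusive: a bin exactly at a cutoff is kept), and the result is inverse
    transformed.  Length, sampling rate and start time are unchanged and the
    output is real.  No tapering or padding is applied; trials carry lead-in /
    lead-out padding so edge ringing stays away from the gait cycle.
    """
    if spec.kind not in ("fft_highpass", "fft_bandpass"):
        raise ValueError("fft_filter handles fft_highpass / fft_bandpass only")
    n = len(x)
    if n < 8:
        raise ValueError("fft_filter needs at least 8 samples")
    nyq = x.fs_hz / 2.0
    low = spec.low_cut_hz
    high = spec.high_cut_hz if spec.kind == "fft_bandpass" else None
    for c in (low, high):
        if c is not None and c >= nyq:
            raise ValueError(f"cutoff {c} Hz >= Nyquist {nyq} Hz")

    spectrum = np.fft.rfft(x.values)
    freqs = np.fft.rfftfreq(n, d=x.dt_s)
    # small relative tolerance so a bin nominally at the cutoff survives rounding
    tol = 1e-9 * x.fs_hz
    keep = freqs >= low - tol
    if high is not None:
        keep &= freqs <= high + tol
    spectrum[~keep] = 0.0
    out = np.fft.irfft(spectrum, n=n)
    return TimeSeries(out, x.fs_hz, x.t0_s)


def fft_highpass(x: TimeSeries, cutoff_hz: float) -> TimeSeries:
    return fft_filter(x, FilterSpec("fft_highpass", low_cut_hz=cutoff_hz))


def fft_bandpass(x: TimeSeries, low_hz: float, high_hz: float) -> TimeSeries:
    return fft_filter(x, FilterSpec("fft_bandpass", low_cut_hz=low_hz, high_cut_hz=high_hz))


def butter_lowpass_zero_lag(x: TimeSeries, cutoff_hz: float, order: int = 4) -> TimeSeries:
    """Forward-backward Butterworth low-pass (effective zero phase).

    ``order`` is the single-pass order; the forward-backward application
    squares the magnitude response and cancels the phase.  Endpoint
    transients are handled by even (reflective) padding long enough —
    several filter time constants, ~6 fs/cutoff samples — for the edge
    transients to decay below 1e-6, which keeps the operation symmetric
    under time reversal.
    """
    if not 0 < cutoff_hz < x.fs_hz / 2.0:
        raise ValueError(f"cutoff {cutoff_hz} Hz outside (0, Nyquist)")
    if order < 1:
        raise ValueError("order must be >= 1")
    b, a = sps.butter(order, cutoff_hz, btype="low", fs=x.fs_hz)
    padlen = min(max(3 * order, int(np.ceil(6.0 * x.fs_hz / cutoff_hz))), len(x) - 1)
    out = sps.filtfilt(b, a, x.values, padtype="even", padlen=padlen)
    return TimeSeries(out, x.fs_hz, x.t0_s)


def resample_linear(x: TimeSeries, target_fs_hz: float) -> TimeSeries:
    """Linear interpolation onto a uniform grid at ``target_fs_hz`` sharing t0.

    The grid covers the original span; the last target sample lies within one
    target-sample interval of the original end point.
    """
    if not target_fs_hz > 0:
        raise ValueError("target sampling frequency must be positive")
    if len(x) < 2:
        raise ValueError("resample needs at least 2 samples")
    n_out = int(np.floor(x.duration_s * target_fs_hz + 1e-9)) + 1
    t_new = np.arange(n_out) / target_fs_hz
    t_old = np.arange(len(x)) / x.fs_hz
    out = np.interp(t_new, t_old, x.values)
    return TimeSeries(out, target_fs_hz, x.t0_s)


def scale_peak_to_peak(x: TimeSeries, reference: TimeSeries) -> TimeSeries:
    """Multiplicatively scale ``x`` so its peak-to-peak range matches ``reference``.

    Gain only — no offset shift; the band-pass upstream already removes means.
    """
    ptp_x = float(np.ptp(x.values))
    ptp_ref = float(np.ptp(reference.values))
    if ptp_x == 0.0 or ptp_ref == 0.0:
        raise ValueError("peak-to-peak scaling undefined for a constant signal")
    return TimeSeries(x.values * (ptp_ref / ptp_x), x.fs_hz, x.t0_s)
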