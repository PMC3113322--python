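"""Synthetic walking cohorts emulating the instrumented-sock recordings.

No public recordings of the sock exist, so the package ships a generator that
reproduces the documented statistical structure of the signals: a sensor
voltage with maxima around heel strike and toe off and minima around heel
lift and mid swing, 0.2-0.4 V peak-to-peak, slow baseline drift,
hysteresis-like rise/fall asymmetry, trial-to-trial timing jitter, a
kinematic (ankle angle) channel that diverges from the sensor by a
controllable amount, force-platform channels defining the gait cycle by their
5 N crossings, and a bench stretch-relax resistance trace with drift.

Every generated trial carries the exact event times used in its construction,
so detector accuracy can be scored against known truth.

The waveform family is a sum of signed asymmetric Gaussians: one bump per
feature (+HS1, -HL, +TO, -mid-swing, +HS2), with a slower falling than rising
width to mimic the viscoelastic relaxation of the knitted structure.  The
kinematic channel shares the same template; mismatch between the two channels
is modelled as subject-fixed per-feature amplitude/phase perturbations plus a
smooth subject-fixed distortion, all scaled by a single ``kinematic_mismatch``
knob, plus a small trial-to-trial wobble tied to the timing jitter.
Subject-fixed components lower the sensor/ankle similarity without harming
detector accuracy — calibrated offsets absorb any repeatable discrepancy —
which is exactly the behaviour reported for subjects whose curves matched the
kinematics poorly yet whose events were still predicted accurately.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .records import ANKLE_FS_HZ, SENSOR_FS_HZ, EventTimes, TrialRecord
from .timeseries import TimeSeries

__all__ = [
    "SubjectProfile",
    "StretchBench",
    "make_profile",
    "simulate_trial",
    "simulate_cohort",
    "simulate_stretch_test",
    "CONDITIONS",
]

CONDITIONS = ("sock_only", "shod")

# feature order used throughout: HS1, HL, TO, mid-swing trough, HS2
FEATURE_SIGNS = np.array([+1.0, -1.0, +1.0, -1.0, +1.0])
DEFAULT_PHASES_PCT = (0.0, 40.0, 60.0, 80.0, 100.0)

PAD_S = 0.6                 # lead-in / lead-out around the cycle (>= 0.5 s)
GRF_PEAK_N = 800.0          # ~1.2 x body weight; only the 5 N crossings matter
ANKLE_PTP_DEG = 20.0        # sagittal ankle excursion of the template
SPURIOUS_PHASE_PCT = 30.0   # early-stance artifact seen in some shod trials


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one subject under one footwear condition."""

    subject_id: str
    condition: str
    cycle_duration_s: float
    peak_to_peak_v: float
    bump_amplitudes_v: Tuple[float, float, float, float, float]
    bump_widths_rise_s: Tuple[float, float, float, float, float]
    bump_widths_fall_s: Tuple[float, float, float, float, float]
    event_phases_pct: Tuple[float, float, float, float, float] = DEFAULT_PHASES_PCT
    drift_rate_v_per_s: float = 0.0
    drift_sine_amp_v: float = 0.0
    drift_sine_freq_hz: float = 0.05
    noise_sd_v: float = 0.0
    timing_jitter_sd_s: float = 0.0
    kinematic_mismatch: float = 0.0
    spurious_peak: bool = False
    spurious_amplitude_frac: float = 0.0
    # subject-fixed unit-scale perturbations, each multiplied by
    # kinematic_mismatch at simulation time.  Most of the divergence sits on
    # the sensor side (sock fit, knit nonlinearity); the ankle channel is a
    # measured joint angle and is perturbed only gently so its pre-swing
    # minimum (the heel-lift reference) always exists.
    ankle_phase_unit_s: Tuple[float, ...] = (0.0,) * 5
    ankle_amp_log_unit: Tuple[float, ...] = (0.0,) * 5
    ankle_distortion_cyc: Tuple[float, ...] = ()      # cycles per gait cycle
    ankle_distortion_amp: Tuple[float, ...] = ()      # fraction of ankle ptp
    ankle_distortion_phase: Tuple[float, ...] = ()
    sensor_phase_unit_s: Tuple[float, ...] = (0.0,) * 5
    sensor_amp_log_unit: Tuple[float, ...] = (0.0,) * 5
    sensor_distortion_cyc: Tuple[float, ...] = ()     # cycles per gait cycle
    sensor_distortion_amp: Tuple[float, ...] = ()     # fraction of sensor ptp
    sensor_distortion_phase: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not self.cycle_duration_s > 0:
            raise ValueError("cycle_duration_s must be positive")
        for name in ("bump_amplitudes_v", "bump_widths_rise_s", "bump_widths_fall_s"):
            vals = getattr(self, name)
            if len(vals) != 5 or any(v < 0 for v in vals):
                raise ValueError(f"{name} must be 5 non-negative values")
        if any(w <= 0 for w in self.bump_widths_rise_s + self.bump_widths_fall_s):
            raise ValueError("bump widths must be positive")
        if self.noise_sd_v < 0 or self.timing_jitter_sd_s < 0:
            raise ValueError("noise and jitter SDs must be non-negative")
        ph = self.event_phases_pct
        if len(ph) != 5 or ph[0] != 0.0 or ph[-1] != 100.0:
            raise ValueError("event phases must run from 0 to 100 %GC")
        if not all(a < b for a, b in zip(ph, ph[1:])):
            raise ValueError("event phases must be strictly increasing")
        if not 0.0 <= self.kinematic_mismatch <= 1.0:
            raise ValueError("kinematic_mismatch must lie in [0, 1]")
        if not 0.0 <= self.spurious_amplitude_frac <= 1.2:
            raise ValueError("spurious peak amplitude fraction must lie in [0, 1.2]")


@dataclass(frozen=True)
class StretchBench:
    """Bench characterization: triangular strain and measured resistance."""

    strain_mm: TimeSeries
    resistance_ohm: TimeSeries
    rate_mm_s: float

    def __post_init__(self) -> None:
        if len(self.strain_mm) != len(self.resistance_ohm):
            raise ValueError("strain and resistance channels must share length")
        if abs(self.strain_mm.fs_hz - self.resistance_ohm.fs_hz) > 1e-9:
            raise ValueError("strain and resistance channels must share sampling rate")


def _subseed(*parts: int) -> int:
    """Deterministic sub-seed from master seed + indices (stable under growth)."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] & 0x7FFFFFFF)


def make_profile(condition: str, seed: int, subject_id: Optional[str] = None) -> SubjectProfile:
    """Draw one subject profile from the documented default distributions.

    Cycle duration ~ Normal(1.1 s, 0.1 s) truncated above 0.6 s; sensor
    peak-to-peak ~ Uniform(0.2, 0.4) V; amplitude noise 5% of peak-to-peak;
    timing jitter SD 10 ms (sock-only) or 15 ms (shod); shod subjects draw a
    larger kinematic mismatch and with probability 0.05 carry a spurious
    early-stance peak.  Deterministic for fixed (condition, seed).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng([int(seed), CONDITIONS.index(condition)])

    cycle = float(rng.normal(1.1, 0.1))
    while cycle <= 0.6:
        cycle = float(rng.normal(1.1, 0.1))

    ptp = float(rng.uniform(0.2, 0.4))
    rel = np.array(
        [
            rng.uniform(0.35, 0.55),   # HS1 peak
            rng.uniform(0.40, 0.60),   # HL trough
            1.0,                       # TO peak (largest feature)
            rng.uniform(0.50, 0.70),   # mid-swing trough (deepest minimum)
            rng.uniform(0.35, 0.55),   # HS2 peak
        ]
    )
    scale = ptp / (rel[2] + rel[3])    # template ptp = TO peak + mid-swing trough
    amps = tuple(float(v) for v in rel * scale)

    rise = rng.uniform(0.045, 0.065, size=5)
    fall = rise * rng.uniform(1.10, 1.22, size=5)  # viscoelastic: slower relaxation

    shod = condition == "shod"
    mismatch = float(rng.uniform(0.25, 0.95)) if shod else float(rng.uniform(0.05, 0.60))
    spurious = bool(shod and rng.random() < 0.05)

    n_dist = 3
    return SubjectProfile(
        subject_id=subject_id or f"subj-{condition}-{seed}",
        condition=condition,
        cycle_duration_s=cycle,
        peak_to_peak_v=ptp,
        bump_amplitudes_v=amps,
        bump_widths_rise_s=tuple(float(v) for v in rise),
        bump_widths_fall_s=tuple(float(v) for v in fall),
        drift_rate_v_per_s=float(rng.normal(0.0, 0.008)),
        drift_sine_amp_v=float(rng.uniform(0.005, 0.015)),
        drift_sine_freq_hz=0.05,
        noise_sd_v=0.05 * ptp,
        timing_jitter_sd_s=0.015 if shod else 0.010,
        kinematic_mismatch=mismatch,
        spurious_peak=spurious,
        spurious_amplitude_frac=float(rng.uniform(0.9, 1.2)) if spurious else 0.0,
        ankle_phase_unit_s=tuple(
            float(v) for v in np.clip(rng.normal(0.0, 0.040, size=5), -0.07, 0.07)
        ),
        ankle_amp_log_unit=tuple(float(v) for v in rng.normal(0.0, 0.30, size=5)),
        ankle_distortion_cyc=tuple(float(v) for v in rng.uniform(1.0, 4.0, size=n_dist)),
        ankle_distortion_amp=tuple(float(v) for v in rng.uniform(0.04, 0.10, size=n_dist)),
        ankle_distortion_phase=tuple(float(v) for v in rng.uniform(0.0, 2 * np.pi, size=n_dist)),
        # lead/lag of the sock features relative to the physical events is
        # capped so features never reorder within the cycle
        sensor_phase_unit_s=tuple(
            float(v) for v in np.clip(rng.normal(0.0, 0.055, size=5), -0.08, 0.08)
        ),
        # the toe-off plantarflexion is the dominant strain feature: its bump
        # may only grow, and the heel-strike bumps may only shrink modestly,
        # so threshold feasibility is lost only through the spurious peak
        sensor_amp_log_unit=tuple(
            float(v)
            for v in np.clip(
                rng.normal(0.0, 0.45, size=5),
                [-0.60, -0.60, -0.05, -0.60, -0.60],
                [0.10, 0.60, 0.60, 0.60, 0.10],
            )
        ),
        sensor_distortion_cyc=tuple(float(v) for v in rng.uniform(0.8, 2.2, size=n_dist)),
        sensor_distortion_amp=tuple(float(v) for v in rng.uniform(0.05, 0.12, size=n_dist)),
        sensor_distortion_phase=tuple(float(v) for v in rng.uniform(0.0, 2 * np.pi, size=n_dist)),
    )


def _asym_gauss(t: np.ndarray, center: float, amp: float, w_rise: float, w_fall: float) -> np.ndarray:
    w = np.where(t < center, w_rise, w_fall)
    return amp * np.exp(-0.5 * ((t - center) / w) ** 2)


def _jittered_event_times(profile: SubjectProfile, rng: np.random.Generator) -> np.ndarray:
    """Event times for one trial: nominal phases plus independent jitter.

    HS1 anchors the cycle (no jitter); the remaining events jitter
    independently, with redraws preserving a 50 ms ordering margin.
    """
    cyc = profile.cycle_duration_s
    nominal = PAD_S + np.asarray(profile.event_phases_pct) / 100.0 * cyc
    times = nominal.copy()
    for k in range(1, 5):
        for _ in range(100):
            t = nominal[k] + rng.normal(0.0, profile.timing_jitter_sd_s)
            if t > times[k - 1] + 0.05:
                times[k] = t
                break
        else:
            times[k] = times[k - 1] + 0.05
    return times


def _grf_channels(
    t: np.ndarray, hs1: float, to: float, hs2: float, t_end: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Smooth stance envelopes whose 5 N crossings sit exactly at the events."""

    def stance(t: np.ndarray, start: float, stop: float) -> np.ndarray:
        out = np.zeros_like(t)
        inside = (t > start) & (t < stop)
        out[inside] = 5.0 + (GRF_PEAK_N - 5.0) * np.sin(
            np.pi * (t[inside] - start) / (stop - start)
        )
        # sub-threshold shoulders so channels are continuous-ish at the edges
        before = t <= start
        after = t >= stop
        out[before] = 5.0 * np.exp(-(((t[before] - start) / 0.02) ** 2))
        out[after] = 5.0 * np.exp(-(((t[after] - stop) / 0.02) ** 2))
        return out

    grf1 = stance(t, hs1, to)
    grf2 = stance(t, hs2, min(hs2 + 0.66 * (hs2 - hs1), t_end + 0.1))
    return grf1, grf2


def simulate_trial(profile: SubjectProfile, trial_seed: int, trial_index: int = 0) -> TrialRecord:
    """Build one gait cycle with lead-in/lead-out padding.

    Deterministic for fixed (profile, trial_seed).  The recorded truth is the
    jittered construction times of HS1, HL, TO and HS2.
    """
    rng = np.random.default_rng([int(trial_seed)])
    cyc = profile.cycle_duration_s
    ev = _jittered_event_times(profile, rng)   # HS1, HL, TO, MID, HS2
    hs1, hl, to, mid, hs2 = (float(x) for x in ev)

    # grids: ankle at 100 Hz, sensor/GRF on the same span at 15x the rate
    n_ankle = int(round((hs2 + PAD_S) * ANKLE_FS_HZ)) + 1
    n_sensor = 15 * (n_ankle - 1) + 1
    t_s = np.arange(n_sensor) / SENSOR_FS_HZ
    t_a = np.arange(n_ankle) / ANKLE_FS_HZ

    m = profile.kinematic_mismatch
    amps = FEATURE_SIGNS * np.asarray(profile.bump_amplitudes_v)
    sensor = np.zeros_like(t_s)
    for k in range(5):
        # subject-fixed sensor-side mismatch: the sock feature leads/lags the
        # physical event by a repeatable amount, so calibration absorbs it
        center = ev[k] + m * profile.sensor_phase_unit_s[k]
        amp = amps[k] * np.exp(m * profile.sensor_amp_log_unit[k])
        sensor += _asym_gauss(
            t_s, center, amp, profile.bump_widths_rise_s[k], profile.bump_widths_fall_s[k]
        )
    phi_s = (t_s - hs1) / cyc
    for cyc_per_gc, amp_frac, phase in zip(
        profile.sensor_distortion_cyc,
        profile.sensor_distortion_amp,
        profile.sensor_distortion_phase,
    ):
        sensor += m * amp_frac * profile.peak_to_peak_v * np.sin(
            2 * np.pi * cyc_per_gc * phi_s + phase
        )
    if profile.spurious_peak:
        # early-stance artifact (shoe roll-over): broader than the gait bumps
        # and with trial-varying magnitude, so it defeats any fixed threshold
        # on at least some trials when it rivals the toe-off peak
        sp_t = hs1 + SPURIOUS_PHASE_PCT / 100.0 * cyc + rng.normal(
            0.0, profile.timing_jitter_sd_s
        )
        sp_amp = (
            profile.spurious_amplitude_frac
            * profile.bump_amplitudes_v[2]
            * float(np.exp(rng.normal(0.0, 0.25)))
        )
        sensor += _asym_gauss(
            t_s,
            sp_t,
            sp_amp,
            1.5 * profile.bump_widths_rise_s[2],
            1.5 * profile.bump_widths_fall_s[2],
        )
    drift_phase = rng.uniform(0.0, 2 * np.pi)
    sensor += 0.3                                    # DC operating point
    sensor += profile.drift_rate_v_per_s * t_s
    sensor += profile.drift_sine_amp_v * np.sin(
        2 * np.pi * profile.drift_sine_freq_hz * t_s + drift_phase
    )
    if profile.noise_sd_v > 0:
        sensor += rng.normal(0.0, profile.noise_sd_v, size=n_sensor)

    # ankle channel: same template in degrees with gentler perturbations
    deg_per_v = ANKLE_PTP_DEG / profile.peak_to_peak_v
    wobble_sd = 0.8 * m * profile.timing_jitter_sd_s   # trial-to-trial part
    ankle = np.full_like(t_a, 5.0)
    for k in range(5):
        center = ev[k] + m * profile.ankle_phase_unit_s[k]
        if wobble_sd > 0:
            center += rng.normal(0.0, wobble_sd)
        amp = amps[k] * deg_per_v * np.exp(m * profile.ankle_amp_log_unit[k])
        # the joint angle does not inherit the sock's viscoelastic rise/fall
        # asymmetry: symmetric bumps with the mean width, so the filtered
        # heel-lift trough stays where it was constructed
        w = 0.5 * (profile.bump_widths_rise_s[k] + profile.bump_widths_fall_s[k])
        ankle += _asym_gauss(t_a, center, amp, w, w)
    phi = (t_a - hs1) / cyc
    for cyc_per_gc, amp_frac, phase in zip(
        profile.ankle_distortion_cyc,
        profile.ankle_distortion_amp,
        profile.ankle_distortion_phase,
    ):
        ankle += m * amp_frac * ANKLE_PTP_DEG * np.sin(2 * np.pi * cyc_per_gc * phi + phase)
    ankle_noise_sd = (profile.noise_sd_v / profile.peak_to_peak_v) * 0.5 * ANKLE_PTP_DEG
    if ankle_noise_sd > 0:
        ankle += rng.normal(0.0, ankle_noise_sd, size=n_ankle)

    grf1, grf2 = _grf_channels(t_s, hs1, to, hs2, t_s[-1])

    return TrialRecord(
        sensor=TimeSeries(sensor, SENSOR_FS_HZ),
        ankle=TimeSeries(ankle, ANKLE_FS_HZ),
        grf1=TimeSeries(grf1, SENSOR_FS_HZ),
        grf2=TimeSeries(grf2, SENSOR_FS_HZ),
        truth=EventTimes(hs1_s=hs1, hl_s=hl, to_s=to, hs2_s=hs2),
        subject_id=profile.subject_id,
        condition=profile.condition,
        trial_index=trial_index,
    )


def simulate_cohort(
    n_subjects: int,
    n_trials: int,
    condition: str,
    seed: int,
    profile_overrides: Optional[dict] = None,
) -> Dict[str, List[TrialRecord]]:
    """Simulate ``n_subjects`` x ``n_trials`` trials grouped by subject.

    Sub-seeds derive deterministically from (master seed, subject index) and
    (master seed, subject index, trial index), so adding subjects or trials
    never reshuffles existing ones.  ``profile_overrides`` replaces fields on
    every drawn profile (e.g. ``{"noise_sd_v": 0.0}`` for degenerate cohorts).
    """
    if n_subjects < 1 or n_trials < 1:
        raise ValueError("n_subjects and n_trials must be >= 1")
    cohort: Dict[str, List[TrialRecord]] = {}
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        profile = make_profile(condition, _subseed(seed, i), subject_id=sid)
        if profile_overrides:
            profile = dataclasses.replace(profile, **profile_overrides)
        cohort[sid] = [
            simulate_trial(profile, _subseed(seed, i, j), trial_index=j)
            for j in range(n_trials)
        ]
    return cohort


def cohort_profiles(
    n_subjects: int, condition: str, seed: int, profile_overrides: Optional[dict] = None
) -> List[SubjectProfile]:
    """The profiles behind :func:`simulate_cohort` with the same sub-seeding."""
    profiles = []
    for i in range(n_subjects):
        p = make_profile(condition, _subseed(seed, i), subject_id=f"S{i + 1:02d}")
        if profile_overrides:
            p = dataclasses.replace(p, **profile_overrides)
        profiles.append(p)
    return profiles


def simulate_stretch_test(
    rate_mm_s: float,
    n_cycles: int,
    seed: int,
    amplitude_mm: float = 9.0,
    fs_hz: float = 100.0,
    gain_ohm_per_mm: float = 20.0,
    baseline_ohm: float = 1000.0,
    drift_ohm: float = -80.0,
    asymmetry_ohm: float = 4.0,
    noise_ohm: float = 1.0,
) -> StretchBench:
    """Bench stretch-relax test of the knitted sensor.

    Strain is a periodic triangle wave at the stated rate; resistance is an
    affine function of strain plus a decaying-exponential baseline drift (the
    resting resistance falls over successive stretches), a rate-direction
    asymmetry term producing a hysteresis loop in resistance-vs-strain, and
    white noise.  High-pass filtering at 0.3 Hz removes the drift and
    recovers a near-linear strain-resistance relationship.
    """
    if not rate_mm_s > 0:
        raise ValueError("stretch rate must be positive")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng([int(seed)])
    period = 2.0 * amplitude_mm / rate_mm_s
    n = int(round(n_cycles * period * fs_hz)) + 1
    t = np.arange(n) / fs_hz
    phase = (t / period) % 1.0
    strain = np.where(phase < 0.5, 2.0 * amplitude_mm * phase, 2.0 * amplitude_mm * (1.0 - phase))
    velocity_sign = np.where(phase < 0.5, 1.0, -1.0)

    tau = max(n_cycles * period / 3.0, period)
    resistance = (
        baseline_ohm
        + gain_ohm_per_mm * strain
        + drift_ohm * (1.0 - np.exp(-t / tau))
        + asymmetry_ohm * velocity_sign
    )
    if noise_ohm > 0:
        resistance += rng.normal(0.0, noise_ohm, size=n)
    return StretchBench(
        strain_mm=TimeSeries(strain, fs_hz),
        resistance_ohm=TimeSeries(resistance, fs_hz),
        rate_mm_s=rate_mm_s,
    )
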