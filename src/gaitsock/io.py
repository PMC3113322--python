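"""Trial-file and parameter-file formats plus run configuration.

Trial files are comma-delimited text with ``#``-prefixed header lines: the
sensor and force-platform channels on the 1500 Hz grid and the ankle angle
populated every 15th row (its true 100 Hz rate), keeping all channels
synchronized in one file.  Floats are rendered with shortest round-trip
precision, so write -> read is the identity on every channel.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, TextIO, Union

import numpy as np

from .events import AlgorithmParams
from .records import ANKLE_FS_HZ, SENSOR_FS_HZ, EventTimes, TrialRecord
from .timeseries import TimeSeries

__all__ = [
    "RunConfig",
    "read_trial",
    "write_trial",
    "read_params",
    "write_params",
    "write_stretch_bench",
]

_RATIO = int(round(SENSOR_FS_HZ / ANKLE_FS_HZ))
_COLUMNS = ("time_s", "sensor_v", "grf1_n", "grf2_n", "ankle_deg")


class TrialFileError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a cohort run."""

    n_subjects: int = 20
    n_trials: int = 10
    condition: str = "sock_only"
    seed: int = 42
    band_low_hz: float = 0.3
    band_high_hz: float = 4.0
    butter_cutoff_hz: float = 6.0
    grf_threshold_n: float = 5.0
    detection_signal: str = "filtered"
    outdir: str = "."

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("subject and trial counts must be >= 1")
        if self.condition not in ("sock_only", "shod"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("band-pass requires 0 < low < high")
        if not self.butter_cutoff_hz > 0 or not self.grf_threshold_n > 0:
            raise ValueError("cutoff and GRF threshold must be positive")
        if self.detection_signal not in ("filtered", "raw"):
            raise ValueError("detection_signal must be 'filtered' or 'raw'")

    def hash(self) -> str:
        payload = repr(sorted(dataclasses.asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _fmt(x: float) -> str:
    return repr(float(x))


def write_trial(trial: TrialRecord, path: Union[str, Path], extra_header: Optional[Dict[str, str]] = None) -> None:
    path = Path(path)
    n = len(trial.sensor)
    with path.open("w") as fh:
        fh.write("# gaitsock-trial v1\n")
        fh.write(f"# subject_id: {trial.subject_id}\n")
        fh.write(f"# condition: {trial.condition}\n")
        fh.write(f"# trial_index: {trial.trial_index}\n")
        fh.write(f"# sensor_fs_hz: {_fmt(trial.sensor.fs_hz)}\n")
        fh.write(f"# ankle_fs_hz: {_fmt(trial.ankle.fs_hz)}\n")
        fh.write(f"# t0_s: {_fmt(trial.sensor.t0_s)}\n")
        if trial.truth is not None:
            for key, val in (
                ("truth_hs1_s", trial.truth.hs1_s),
                ("truth_hl_s", trial.truth.hl_s),
                ("truth_to_s", trial.truth.to_s),
                ("truth_hs2_s", trial.truth.hs2_s),
            ):
                if val is not None:
                    fh.write(f"# {key}: {_fmt(val)}\n")
        for key, val in (extra_header or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write(",".join(_COLUMNS) + "\n")
        times = trial.sensor.times()
        for i in range(n):
            ankle = _fmt(trial.ankle.values[i // _RATIO]) if i % _RATIO == 0 and i // _RATIO < len(trial.ankle) else ""
            fh.write(
                f"{_fmt(times[i])},{_fmt(trial.sensor.values[i])},"
                f"{_fmt(trial.grf1.values[i])},{_fmt(trial.grf2.values[i])},{ankle}\n"
            )


def read_trial(path: Union[str, Path]) -> TrialRecord:
    path = Path(path)
    header: Dict[str, str] = {}
    rows = []
    columns = None
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    header[k.strip()] = v.strip()
                continue
            parts = line.split(",")
            if columns is None:
                columns = tuple(p.strip() for p in parts)
                missing = [c for c in _COLUMNS if c not in columns]
                if missing:
                    raise TrialFileError(f"missing column(s): {', '.join(missing)}")
                continue
            if len(parts) != len(columns):
                raise TrialFileError(f"ragged row with {len(parts)} fields")
            rows.append(parts)
    if columns is None or not rows:
        raise TrialFileError("no data block found")

    for key in ("subject_id", "condition", "trial_index", "sensor_fs_hz", "ankle_fs_hz"):
        if key not in header:
            raise TrialFileError(f"missing header key: {key}")

    idx = {c: columns.index(c) for c in _COLUMNS}
    data = np.array([[r[idx[c]] if r[idx[c]] else "nan" for c in _COLUMNS] for r in rows], dtype=float)
    times = data[:, 0]
    if np.any(np.diff(times) <= 0):
        raise TrialFileError("non-monotone time column")
    t0 = float(header.get("t0_s", times[0]))
    fs_sensor = float(header["sensor_fs_hz"])
    fs_ankle = float(header["ankle_fs_hz"])
    ankle_vals = data[:, 4][~np.isnan(data[:, 4])]

    truth = None
    if "truth_hs1_s" in header:
        truth = EventTimes(
            hs1_s=float(header["truth_hs1_s"]),
            hl_s=float(header["truth_hl_s"]) if "truth_hl_s" in header else None,
            to_s=float(header["truth_to_s"]),
            hs2_s=float(header["truth_hs2_s"]),
        )
    return TrialRecord(
        sensor=TimeSeries(data[:, 1], fs_sensor, t0),
        ankle=TimeSeries(ankle_vals, fs_ankle, t0),
        grf1=TimeSeries(data[:, 2], fs_sensor, t0),
        grf2=TimeSeries(data[:, 3], fs_sensor, t0),
        truth=truth,
        subject_id=header["subject_id"],
        condition=header["condition"],
        trial_index=int(header["trial_index"]),
    )


def write_params(params: AlgorithmParams, path: Union[str, Path], extra_header: Optional[Dict[str, str]] = None) -> None:
    with Path(path).open("w") as fh:
        fh.write("# gaitsock-params v1 (a1 in volts, a2-a5 in seconds)\n")
        for key, val in (extra_header or {}).items():
            fh.write(f"# {key}: {val}\n")
        for k, v in params.as_dict().items():
            fh.write(f"{k}={_fmt(v)}\n")


def read_params(path: Union[str, Path]) -> AlgorithmParams:
    vals: Dict[str, float] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            vals[k.strip()] = float(v)
    missing = [k for k in ("a1", "a2", "a3", "a4", "a5") if k not in vals]
    if missing:
        raise TrialFileError(f"params file missing: {', '.join(missing)}")
    return AlgorithmParams(**vals)


def write_stretch_bench(bench, path: Union[str, Path], extra_header: Optional[Dict[str, str]] = None) -> None:
    """3-column delimited file: time_s, strain_mm, resistance_ohm."""
    with Path(path).open("w") as fh:
        fh.write("# gaitsock-bench v1\n")
        fh.write(f"# rate_mm_s: {_fmt(bench.rate_mm_s)}\n")
        for key, val in (extra_header or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("time_s,strain_mm,resistance_ohm\n")
        times = bench.strain_mm.times()
        for i in range(len(bench.strain_mm)):
            fh.write(
                f"{_fmt(times[i])},{_fmt(bench.strain_mm.values[i])},"
                f"{_fmt(bench.resistance_ohm.values[i])}\n"
            )
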