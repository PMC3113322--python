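"""Model/Results interface over the detector pipeline.

``SubjectGaitModel`` treats one subject's trials under one footwear condition
as the data and the five detector parameters as the quantities to estimate:
``fit()`` calibrates on the training trials and returns a
``SubjectGaitResults`` carrying the estimates, their across-trial spreads,
test-set predictions, the %gait-cycle error report and a text ``summary()``.
``CohortStudy`` runs the same fit over every subject of a cohort and exposes
the cohort accuracy and similarity tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .events import (
    AlgorithmParams,
    CalibrationDiagnostics,
    CalibrationInfeasible,
    DetectionResult,
    calibrate_detailed,
    detect_events,
)
from .evaluate import (
    EVENTS,
    ErrorReport,
    cohort_table,
    evaluate_subject,
    extract_truth,
    render_table,
)
from .records import EventTimes, TrialRecord
from .similarity import SimilarityResult, subject_similarity
from .synthcohort import simulate_cohort

__all__ = ["SubjectGaitModel", "SubjectGaitResults", "CohortStudy", "CohortResults"]


class SubjectGaitModel:
    """Detector calibration model for one subject/condition.

    Parameters
    ----------
    trials : sequence of TrialRecord
        Ordered trials of a single subject under a single condition; the
        first ``n_train`` are used for calibration, the rest for scoring.
    n_train : int
        Number of training trials (default 5).
    filtered : bool
        Run detection on the 0.3-4 Hz band-passed voltage (default) or raw.
    """

    def __init__(self, trials: Sequence[TrialRecord], n_train: int = 5, filtered: bool = True):
        if len(trials) <= n_train:
            raise ValueError("need more trials than the training split")
        if len({t.subject_id for t in trials}) != 1 or len({t.condition for t in trials}) != 1:
            raise ValueError("trials must come from a single subject and condition")
        self.trials = list(trials)
        self.n_train = n_train
        self.filtered = filtered
        self.subject_id = trials[0].subject_id
        self.condition = trials[0].condition

    def fit(self) -> "SubjectGaitResults":
        truths = [extract_truth(t) for t in self.trials]
        params: Optional[AlgorithmParams] = None
        diag: Optional[CalibrationDiagnostics] = None
        predictions: List[DetectionResult] = []
        from .events import GaitEventError

        try:
            params, diag = calibrate_detailed(
                list(zip(self.trials[: self.n_train], truths[: self.n_train])),
                filtered=self.filtered,
            )
            for trial, truth in zip(self.trials[self.n_train :], truths[self.n_train :]):
                predictions.append(
                    detect_events(trial.sensor, params, truth.hs1_s, filtered=self.filtered)
                )
        except GaitEventError:
            params, diag, predictions = None, None, []
        report = evaluate_subject(self.trials, n_train=self.n_train, filtered=self.filtered)
        similarity = subject_similarity(list(zip(self.trials, truths)))
        return SubjectGaitResults(
            model=self,
            params=params,
            diagnostics=diag,
            truths=truths,
            predictions=predictions,
            error_report=report,
            similarity=similarity,
        )


@dataclass
class SubjectGaitResults:
    """Fit outcome for one subject: parameter estimates, spreads and errors."""

    model: SubjectGaitModel
    params: Optional[AlgorithmParams]
    diagnostics: Optional[CalibrationDiagnostics]
    truths: List[EventTimes]
    predictions: List[DetectionResult]
    error_report: ErrorReport
    similarity: SimilarityResult

    @property
    def infeasible(self) -> bool:
        return self.params is None

    def params_frame(self) -> pd.DataFrame:
        """Estimates and across-trial SDs of the calibrated parameters."""
        if self.infeasible:
            raise CalibrationInfeasible("calibration-infeasible: no parameters to report")
        sds = self.diagnostics.offset_sd()
        rows = []
        units = {"a1": "V", "a2": "s", "a3": "s", "a4": "s", "a5": "s"}
        for k, v in self.params.as_dict().items():
            rows.append(
                {
                    "param": k,
                    "estimate": v,
                    "sd": float(np.std(self.diagnostics.a1_candidates, ddof=1))
                    if k == "a1"
                    else sds.get(k, np.nan),
                    "unit": units[k],
                }
            )
        return pd.DataFrame(rows).set_index("param")

    def summary(self) -> str:
        lines = [
            "Gait event detector fit",
            "=" * 52,
            f"subject: {self.model.subject_id}    condition: {self.model.condition}",
            f"trials: {len(self.model.trials)} ({self.model.n_train} train / "
            f"{len(self.model.trials) - self.model.n_train} test)",
            f"signal similarity: r = {self.similarity.r:.2f}, "
            f"nMAD = {self.similarity.nmad:.2f}",
        ]
        if self.infeasible:
            lines += ["", "calibration infeasible: no threshold isolates the toe-off rise"]
            return "\n".join(lines)
        lines += ["", "parameters (estimate +/- across-trial SD):"]
        for k, row in self.params_frame().iterrows():
            lines.append(
                f"  {k} = {row['estimate']:+.4f} {row['unit']}"
                + ("" if np.isnan(row["sd"]) else f"  (+/- {row['sd']:.4f})")
            )
        lines += ["", "test-set error (% gait cycle, mean |err| / SD of signed err):"]
        for e in EVENTS:
            lines.append(
                f"  {e}: {self.error_report.mean_abs_pct_gc[e]:.1f} / "
                f"{self.error_report.sd_pct_gc[e]:.1f}"
            )
        return "\n".join(lines)

    def plot_trial(self, test_index: int = 0, ax=None):
        """Plot a test trial's prepared sensor signal with true/predicted events."""
        import matplotlib.pyplot as plt

        from .events import prepare_detection_signal

        trial = self.model.trials[self.model.n_train + test_index]
        truth = self.truths[self.model.n_train + test_index]
        x = prepare_detection_signal(trial.sensor, filtered=self.model.filtered)
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        ax.plot(x.times(), x.values, lw=0.8, label="prepared sensor")
        for t, lbl in ((truth.hl_s, "HL"), (truth.to_s, "TO"), (truth.hs2_s, "HS")):
            ax.axvline(t, color="k", ls="--", lw=0.7)
            ax.text(t, ax.get_ylim()[1], lbl, ha="center", va="bottom", fontsize=8)
        if not self.infeasible and test_index < len(self.predictions):
            det = self.predictions[test_index]
            ax.plot(
                [det.hl_s, det.to_s, det.hs_s],
                [np.interp(t, x.times(), x.values) for t in (det.hl_s, det.to_s, det.hs_s)],
                "rv",
                label="predicted",
            )
        ax.set_xlabel("time (s)")
        ax.set_ylabel("voltage (V)")
        ax.legend(loc="lower right", fontsize=8)
        return ax


class CohortStudy:
    """Fit the detector across every subject of a cohort."""

    def __init__(self, cohort: Dict[str, List[TrialRecord]], n_train: int = 5, filtered: bool = True):
        if not cohort:
            raise ValueError("empty cohort")
        self.cohort = cohort
        self.n_train = n_train
        self.filtered = filtered

    @classmethod
    def simulate(
        cls,
        n_subjects: int,
        n_trials: int,
        condition: str,
        seed: int,
        profile_overrides: Optional[dict] = None,
        n_train: int = 5,
    ) -> "CohortStudy":
        cohort = simulate_cohort(
            n_subjects, n_trials, condition, seed, profile_overrides=profile_overrides
        )
        return cls(cohort, n_train=n_train)

    def fit(self) -> "CohortResults":
        results = {
            sid: SubjectGaitModel(trials, n_train=self.n_train, filtered=self.filtered).fit()
            for sid, trials in self.cohort.items()
        }
        return CohortResults(study=self, subject_results=results)


@dataclass
class CohortResults:
    study: CohortStudy
    subject_results: Dict[str, SubjectGaitResults]

    @property
    def reports(self) -> List[ErrorReport]:
        return [r.error_report for r in self.subject_results.values()]

    def table(self) -> pd.DataFrame:
        """Accuracy table (Mean/Std per event, %GC) with an Average row."""
        return cohort_table(self.reports)

    def similarity_table(self) -> pd.DataFrame:
        rows = {
            sid: {"r": r.similarity.r, "nMAD": r.similarity.nmad}
            for sid, r in self.subject_results.items()
        }
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.loc["Mean"] = df.mean(axis=0)
        df.index.name = "Subject"
        return df

    def summary(self) -> str:
        tab = self.table()
        avg = tab.loc["Average"]
        n_inf = sum(r.infeasible for r in self.reports)
        lines = [
            "Cohort gait event detection",
            "=" * 52,
            f"subjects: {len(self.subject_results)}   infeasible: {n_inf}",
            "",
            "cohort-average test error (% gait cycle):",
        ]
        for e in EVENTS:
            lines.append(f"  {e}: mean |err| {avg[f'Mean {e}']:.1f}, SD {avg[f'Std {e}']:.1f}")
        lines += ["", render_table(tab).rstrip()]
        return "\n".join(lines)
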