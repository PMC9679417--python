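"""The locked-vs-adaptive audit protocol.

One run of the protocol over B buckets:

* a single *locked* model is fitted on the pre-cutoff pool and evaluated,
  unchanged, on every bucket (B locked reports from one fit);
* for each test bucket j, the remaining buckets are added to the locked
  pool cumulatively and chronologically, and a fresh *adaptive* model is
  retrained from scratch at each of the B-1 stages and evaluated on bucket
  j (B x (B-1) adaptive reports — 20 when B = 5).

Every evaluation is leakage-checked: a drug id may never appear in both
the training set and the test bucket of the same evaluation.  The per-test-
bucket *average MCC* is the mean over the adaptive stages only (the locked
baseline is excluded; this choice is recorded in the result metadata).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import DeepDILIModel, EnsembleConfig, child_seed, fit_deepdili
from .metrics import MetricReport, metric_report
from .roster import Roster
from .timesplit import AdaptiveSchedule, SplitPlan, build_adaptive_schedule

__all__ = [
    "StageReport",
    "AdaptabilityResult",
    "run_locked",
    "run_adaptive",
    "summarize",
    "classify_trend",
    "to_metric_rows",
]


class LeakageError(RuntimeError):
    """A drug id appeared in both the training set and the test bucket."""


@dataclass(frozen=True)
class StageReport:
    """One adaptive evaluation: which buckets were added, and how it scored."""

    stage: int                    # 1-based stage within the schedule
    added_buckets: tuple[int, ...]
    added_label: str              # e.g. "+1997-1998+1999-2001"
    train_size: int
    report: MetricReport
    train_ids: frozenset = frozenset()   # drug ids trained on, for leakage audits
    test_ids: frozenset = frozenset()


@dataclass(frozen=True)
class AdaptabilityResult:
    """The full (test bucket x training stage) grid of one protocol run."""

    bucket_labels: tuple[str, ...]
    locked_reports: tuple[MetricReport, ...]
    adaptive_reports: tuple[tuple[StageReport, ...], ...]
    average_adaptive_mcc: tuple[float, ...]
    undefined_mcc_count: int
    config: EnsembleConfig
    seed: int
    average_includes_locked: bool = False  # provenance of the averaging rule

    @property
    def n_buckets(self) -> int:
        return len(self.locked_reports)


def _check_leakage(train: Roster, test: Roster) -> None:
    shared = set(train.drug_ids) & set(test.drug_ids)
    if shared:
        raise LeakageError(
            f"{len(shared)} drug ids shared between training set and test "
            f"bucket, e.g. {sorted(shared)[:5]}"
        )


def _evaluate(model: DeepDILIModel, test: Roster) -> MetricReport:
    scores, labels = model.predict(test)
    return metric_report(test.labels, labels, scores)


def run_locked(
    split: SplitPlan, config: EnsembleConfig
) -> tuple[DeepDILIModel, tuple[MetricReport, ...]]:
    """Fit the locked model once and evaluate it on every bucket.

    The same fitted model is reused across buckets — the locked contract:
    identical inputs yield identical outputs regardless of evaluation order.
    """
    model = fit_deepdili(
        split.locked_pool, config.with_seed(child_seed(config.seed, "locked"))
    )
    reports = []
    for bucket in split.buckets:
        _check_leakage(split.locked_pool, bucket)
        reports.append(_evaluate(model, bucket))
    return model, tuple(reports)


def run_adaptive(split: SplitPlan, config: EnsembleConfig) -> AdaptabilityResult:
    """Execute the full locked-vs-adaptive protocol on a split plan.

    For every test bucket, each schedule stage retrains a fresh model from
    scratch on locked pool + added buckets (no warm starts) and evaluates
    it on the held-out bucket.  Returns the complete grid with locked
    baselines and per-bucket average adaptive MCCs.
    """
    B = split.n_buckets
    if B < 2:
        raise ValueError("need at least two buckets for the adaptive protocol")
    _, locked_reports = run_locked(split, config)

    all_stage_reports: list[tuple[StageReport, ...]] = []
    averages: list[float] = []
    undefined = 0
    for j in range(1, B + 1):
        test_bucket = split.buckets[j - 1]
        schedule: AdaptiveSchedule = build_adaptive_schedule(B, j)
        stage_reports = []
        for k, added in enumerate(schedule.stages, start=1):
            train = split.locked_pool.concat(*(split.buckets[b - 1] for b in added))
            _check_leakage(train, test_bucket)
            model = fit_deepdili(
                train, config.with_seed(child_seed(config.seed, "adaptive", j, k))
            )
            stage_reports.append(
                StageReport(
                    stage=k,
                    added_buckets=added,
                    added_label="".join(f"+{split.bucket_spec.label(b - 1)}" for b in added),
                    train_size=len(train),
                    report=_evaluate(model, test_bucket),
                    train_ids=frozenset(train.drug_ids),
                    test_ids=frozenset(test_bucket.drug_ids),
                )
            )
        mccs = [s.report.mcc for s in stage_reports]
        finite = [m for m in mccs if not math.isnan(m)]
        undefined += len(mccs) - len(finite)
        averages.append(float(np.mean(finite)) if finite else math.nan)
        all_stage_reports.append(tuple(stage_reports))

    return AdaptabilityResult(
        bucket_labels=tuple(split.bucket_spec.label(i) for i in range(B)),
        locked_reports=locked_reports,
        adaptive_reports=tuple(all_stage_reports),
        average_adaptive_mcc=tuple(averages),
        undefined_mcc_count=undefined,
        config=config,
        seed=config.seed,
    )


def classify_trend(
    mccs, slope_tol: float = 0.02, range_tol: float = 0.05
) -> str:
    """Classify a per-stage MCC sequence as improving/flat/declining/wave.

    Rule: if max-min < ``range_tol`` the sequence is "flat".  Otherwise the
    least-squares slope per stage must exceed ``slope_tol`` in magnitude
    *and* the total counter-movement (sum of steps against the slope's
    direction) must stay below half the range for "improving"/"declining";
    any other shape — oscillation comparable to the range, or a negligible
    slope — is a "wave".
    """
    vals = np.asarray([m for m in mccs if not math.isnan(m)], dtype=float)
    if vals.size == 0:
        return "undefined"
    rng = vals.max() - vals.min()
    if rng < range_tol or vals.size == 1:
        return "flat"
    slope = np.polyfit(np.arange(vals.size), vals, 1)[0]
    steps = np.diff(vals)
    if slope > slope_tol and -steps[steps < 0].sum() <= 0.5 * rng:
        return "improving"
    if slope < -slope_tol and steps[steps > 0].sum() <= 0.5 * rng:
        return "declining"
    return "wave"


def summarize(
    result: AdaptabilityResult, slope_tol: float = 0.02, range_tol: float = 0.05
) -> pd.DataFrame:
    """Per-test-bucket summary: locked vs adaptive MCCs, mean, delta, trend.

    ``delta_locked_minus_best`` is locked MCC minus the best adaptive MCC:
    positive means no retraining stage beat the locked baseline on that
    bucket.
    """
    rows = []
    for i in range(result.n_buckets):
        stage_mccs = [s.report.mcc for s in result.adaptive_reports[i]]
        best = np.nanmax(stage_mccs) if np.isfinite(stage_mccs).any() else math.nan
        row = {
            "test_bucket": i + 1,
            "bucket_label": result.bucket_labels[i],
            "locked_mcc": result.locked_reports[i].mcc,
            "mean_adaptive_mcc": result.average_adaptive_mcc[i],
            "delta_locked_minus_best": result.locked_reports[i].mcc - best,
            "trend": classify_trend(stage_mccs, slope_tol, range_tol),
        }
        for s in result.adaptive_reports[i]:
            row[f"mcc_stage{s.stage}"] = s.report.mcc
        rows.append(row)
    return pd.DataFrame(rows)


def to_metric_rows(result: AdaptabilityResult):
    """Flatten a result into (test_bucket, stage, report) rows for the table
    writer; stage 0 is the locked baseline."""
    rows = []
    for i in range(result.n_buckets):
        rows.append((i + 1, 0, result.locked_reports[i]))
        for s in result.adaptive_reports[i]:
            rows.append((i + 1, s.stage, s.report))
    return rows
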