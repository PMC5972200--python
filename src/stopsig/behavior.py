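"""Behavioural summaries, quantile-method SSRT, and QC exclusion rules."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import (GO, STOP, GO_CORRECT, GO_ERROR, GO_MISS, STOP_SUCCESS,
                   STOP_FAIL, SessionLog)


@dataclass
class PerformanceSummary:
    subject_id: str
    correct_go_rts: np.ndarray
    n_go: int
    n_stop: int
    go_correct_frac: float
    go_error_frac: float
    go_miss_frac: float
    stop_success_frac: float
    mean_ssd: float
    ssrt: float
    qc_pass: bool = True
    qc_reasons: list[int] = field(default_factory=list)


def estimate_ssrt(correct_go_rts, fail_frac: float, mean_ssd: float) -> float:
    """Quantile-method SSRT.

    Correct-go RTs are sorted ascending; the RT at the proportion of failed
    inhibitions is the quantile RT (1-based rank ceil(p*n), rank 0 mapped to
    1, no interpolation); SSRT = quantile RT - mean SSD.
    """
    rts = np.sort(np.asarray(correct_go_rts, dtype=float))
    n = rts.size
    if n == 0:
        raise ValueError("need at least one correct go RT")
    if not (0.0 <= fail_frac <= 1.0):
        raise ValueError("fail_frac must lie in [0, 1]")
    raw = fail_frac * n
    nearest = round(raw)
    # guard float fuzz at integer ranks (e.g. 0.4 * 5)
    rank = nearest if abs(raw - nearest) < 1e-9 else math.ceil(raw)
    rank = min(max(rank, 1), n)
    return float(rts[rank - 1]) - float(mean_ssd)


def summarize_performance(log: SessionLog) -> PerformanceSummary:
    """Per-subject performance: fractions over their natural denominators,
    mean SSD over all stop trials, quantile SSRT, and QC flags."""
    if not log.trials:
        raise ValueError("empty session log")
    go = [t for t in log.trials if t.trial_type == GO]
    stop = [t for t in log.trials if t.trial_type == STOP]
    n_go, n_stop = len(go), len(stop)
    correct_rts = np.array([t.rt_ms for t in go if t.outcome == GO_CORRECT],
                           dtype=float)
    go_correct = (sum(t.outcome == GO_CORRECT for t in go) / n_go) if n_go else float("nan")
    go_error = (sum(t.outcome == GO_ERROR for t in go) / n_go) if n_go else float("nan")
    go_miss = (sum(t.outcome == GO_MISS for t in go) / n_go) if n_go else float("nan")
    stop_success = (sum(t.outcome == STOP_SUCCESS for t in stop) / n_stop) if n_stop else float("nan")
    mean_ssd = float(np.mean([t.ssd_ms for t in stop])) if n_stop else float("nan")
    if correct_rts.size and n_stop:
        ssrt = estimate_ssrt(correct_rts, 1.0 - stop_success, mean_ssd)
    else:
        ssrt = float("nan")
    summary = PerformanceSummary(
        subject_id=log.subject_id, correct_go_rts=correct_rts,
        n_go=n_go, n_stop=n_stop,
        go_correct_frac=go_correct, go_error_frac=go_error,
        go_miss_frac=go_miss, stop_success_frac=stop_success,
        mean_ssd=mean_ssd, ssrt=ssrt)
    summary.qc_pass, summary.qc_reasons = qc_exclude(summary)
    return summary


def qc_exclude(summary: PerformanceSummary) -> tuple[bool, list[int]]:
    """Apply the five exclusion rules (strict inequalities, boundaries pass).

    1. stop-trial accuracy < 25% or > 75%
    2. correct go trials < 60%
    3. go error responses > 10%
    4. go misses > 20%
    5. SSRT negative or < 50 ms
    """
    reasons: list[int] = []
    if summary.stop_success_frac < 0.25 or summary.stop_success_frac > 0.75:
        reasons.append(1)
    if summary.go_correct_frac < 0.60:
        reasons.append(2)
    if summary.go_error_frac > 0.10:
        reasons.append(3)
    if summary.go_miss_frac > 0.20:
        reasons.append(4)
    if summary.ssrt < 50.0:  # covers negative values
        reasons.append(5)
    return (len(reasons) == 0, reasons)


def cohort_summary_table(summaries: list[PerformanceSummary]) -> pd.DataFrame:
    """One row per subject with task-performance columns."""
    rows = [{
        "subject_id": s.subject_id,
        "correct_go_rt_ms": float(np.mean(s.correct_go_rts)) if s.correct_go_rts.size else float("nan"),
        "go_error_frac": s.go_error_frac,
        "go_miss_frac": s.go_miss_frac,
        "stop_success_frac": s.stop_success_frac,
        "mean_ssd_ms": s.mean_ssd,
        "ssrt_ms": s.ssrt,
        "qc_pass": s.qc_pass,
        "qc_reasons": ";".join(map(str, s.qc_reasons)),
    } for s in summaries]
    return pd.DataFrame(rows)
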