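"""BIDS-like events TSV round-tripping.

Files are tab-separated with ``n/a`` for missing values; onsets, durations,
response times and SSDs are in seconds on disk and milliseconds in memory.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .task import SessionLog, TaskConfig, TrialRecord, STOP

_COLUMNS = ["onset", "duration", "trial_type", "response", "response_time",
            "ssd", "staircase", "outcome", "run", "block", "null_after"]


def events_frame(log: SessionLog) -> pd.DataFrame:
    rows = []
    for t in log.trials:
        rows.append({
            "onset": t.onset_ms / 1000.0,
            "duration": log.config.go_stim_ms / 1000.0,
            "trial_type": t.trial_type,
            "response": t.response,
            "response_time": None if t.rt_ms is None else t.rt_ms / 1000.0,
            "ssd": None if t.ssd_ms is None else t.ssd_ms / 1000.0,
            "staircase": t.staircase_id,
            "outcome": t.outcome,
            "run": t.run,
            "block": t.block,
            "null_after": t.null_after_ms / 1000.0,
        })
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_events(path, log: SessionLog) -> None:
    events_frame(log).to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path, subject_id: str = "unknown",
                config: TaskConfig | None = None) -> SessionLog:
    """Parse an events TSV back into a SessionLog; malformed rows are
    reported with their (1-based, header-inclusive) line numbers."""
    df = pd.read_csv(path, sep="\t", na_values=["n/a"], keep_default_na=False)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    cfg = config or TaskConfig()
    trials: list[TrialRecord] = []
    for i, row in df.iterrows():
        line = i + 2  # header line is 1
        onset = float(row["onset"])
        if not math.isfinite(onset) or onset < 0:
            raise ValueError(f"{path}, line {line}: invalid onset {row['onset']!r}")
        rt = row["response_time"]
        ssd = row["ssd"]
        trials.append(TrialRecord(
            trial_index=int(i),
            trial_type=str(row["trial_type"]),
            run=int(row["run"]),
            block=int(row["block"]),
            onset_ms=onset * 1000.0,
            null_after_ms=float(row["null_after"]) * 1000.0,
            ssd_ms=None if pd.isna(ssd) else float(ssd) * 1000.0,
            staircase_id=None if pd.isna(row["staircase"]) else str(row["staircase"]),
            response=None if pd.isna(row["response"]) else str(row["response"]),
            rt_ms=None if pd.isna(rt) else float(rt) * 1000.0,
            outcome=None if pd.isna(row["outcome"]) else str(row["outcome"]),
        ))
    return SessionLog(subject_id=subject_id, trials=trials, config=cfg)
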