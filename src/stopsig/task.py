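"""Stop-signal task engine: trial sequences, SSD staircases, race-model runs.

The task is 75% go / 25% stop.  On stop trials a stop signal appears after
an adaptive stop-signal delay (SSD) drawn from one of two interleaved
one-up/one-down staircases (starting at 250 and 350 ms, 50 ms steps):
a successful stop raises the SSD by one step, a failed stop lowers it,
which tracks the ~50% inhibition point.  Responses follow the independent
horse-race model: the response is inhibited iff the stop process
(SSD + SSRT) finishes before the go process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .cohort import SubjectParams, sample_ex_gaussian

GO = "go"
STOP = "stop"

GO_CORRECT = "go_correct"
GO_ERROR = "go_error"
GO_MISS = "go_miss"
STOP_SUCCESS = "stop_success"
STOP_FAIL = "stop_fail"

_STOP_OUTCOMES = (STOP_SUCCESS, STOP_FAIL)


@dataclass(frozen=True)
class TaskConfig:
    n_runs: int = 2
    blocks_per_run: int = 2
    go_per_block: int = 36
    stop_per_block: int = 12
    go_stim_ms: float = 1000.0
    null_min_ms: float = 500.0
    null_max_ms: float = 4000.0
    null_mean_ms: float = 1000.0
    staircase_starts_ms: tuple[float, float] = (250.0, 350.0)
    staircase_step_ms: float = 50.0
    ssrt_jitter_sd_ms: float = 0.0  # Gaussian jitter on the stop process

    def __post_init__(self) -> None:
        if min(self.n_runs, self.blocks_per_run) < 1:
            raise ValueError("need at least one run and one block")
        if self.go_per_block < 0 or self.stop_per_block < 0:
            raise ValueError("trial counts must be non-negative")
        if not (self.null_min_ms < self.null_mean_ms < self.null_max_ms):
            raise ValueError("null gaps require min < mean < max")
        if self.go_stim_ms <= 0 or self.staircase_step_ms <= 0:
            raise ValueError("durations must be positive")

    @property
    def trials_per_block(self) -> int:
        return self.go_per_block + self.stop_per_block

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.blocks_per_run * self.trials_per_block


@dataclass(frozen=True)
class StaircaseState:
    staircase_id: str
    current_ssd: float
    history: tuple[tuple[float, str], ...] = ()


@dataclass
class TrialRecord:
    trial_index: int
    trial_type: str
    run: int
    block: int
    onset_ms: float
    null_after_ms: float
    ssd_ms: float | None = None
    staircase_id: str | None = None
    response: str | None = None
    rt_ms: float | None = None
    outcome: str | None = None


@dataclass
class SessionLog:
    subject_id: str
    trials: list[TrialRecord]
    config: TaskConfig
    run_duration_ms: float | None = None


# ---------------------------------------------------------------------------
# Null-gap sampler: exponential truncated to [min, max], calibrated so that
# the truncated mean equals the requested mean.
# ---------------------------------------------------------------------------

def truncated_exp_rate(low: float, high: float, mean: float) -> float:
    """Rate of an exponential truncated to [low, high] with the given mean.

    The truncated mean m(l) = low + 1/l - w*exp(-l*w)/(1-exp(-l*w)) with
    w = high - low decreases from (low+high)/2 (l -> 0) to low (l -> inf);
    the root is found by bisection.
    """
    if not (low < mean < (low + high) / 2.0):
        raise ValueError("mean must lie in (low, (low+high)/2)")
    w = high - low

    def trunc_mean(lam: float) -> float:
        ew = math.exp(-lam * w)
        return low + 1.0 / lam - w * ew / (1.0 - ew)

    return brentq(lambda lam: trunc_mean(lam) - mean, 1e-9, 1.0, xtol=1e-14)


def sample_null_gaps(rng: np.random.Generator, n: int,
                     low: float = 500.0, high: float = 4000.0,
                     mean: float = 1000.0) -> np.ndarray:
    """Inverse-CDF draws from the calibrated truncated exponential (ms)."""
    lam = truncated_exp_rate(low, high, mean)
    u = rng.uniform(size=n)
    mass = 1.0 - math.exp(-lam * (high - low))
    return low - np.log1p(-u * mass) / lam


# ---------------------------------------------------------------------------
# Sequence generation and staircase updates
# ---------------------------------------------------------------------------

def generate_trial_sequence(config: TaskConfig, seed: int = 0) -> list[TrialRecord]:
    """Pre-execution trial list: per block, go/stop trials shuffled together,
    stop trials split evenly between the two staircases in shuffled order,
    onsets laid out with truncated-exponential null gaps."""
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    idx = 0
    for run in range(config.n_runs):
        onset = 0.0
        for block in range(config.blocks_per_run):
            types = [GO] * config.go_per_block + [STOP] * config.stop_per_block
            rng.shuffle(types)
            # Even split of stop trials over the two staircases, order shuffled.
            n_stop = config.stop_per_block
            assign = ["A"] * (n_stop - n_stop // 2) + ["B"] * (n_stop // 2)
            rng.shuffle(assign)
            gaps = sample_null_gaps(rng, len(types), config.null_min_ms,
                                    config.null_max_ms, config.null_mean_ms)
            a_iter = iter(assign)
            for t, gap in zip(types, gaps):
                rec = TrialRecord(trial_index=idx, trial_type=t, run=run,
                                  block=block, onset_ms=onset,
                                  null_after_ms=float(gap))
                if t == STOP:
                    rec.staircase_id = next(a_iter)
                trials.append(rec)
                onset += config.go_stim_ms + float(gap)
                idx += 1
    return trials


def staircase_update(state: StaircaseState, outcome: str,
                     step_ms: float = 50.0,
                     max_ssd_ms: float = 1000.0) -> StaircaseState:
    """One-up/one-down SSD update, clamped to [0, max_ssd_ms]."""
    if outcome not in _STOP_OUTCOMES:
        raise ValueError(f"not a stop outcome: {outcome!r}")
    delta = step_ms if outcome == STOP_SUCCESS else -step_ms
    new_ssd = min(max(state.current_ssd + delta, 0.0), max_ssd_ms)
    return StaircaseState(staircase_id=state.staircase_id,
                          current_ssd=new_ssd,
                          history=state.history + ((state.current_ssd, outcome),))


def simulate_session(params: SubjectParams, config: TaskConfig | None = None,
                     seed: int = 0) -> SessionLog:
    """Execute the task for one subject under the independent race model.

    Go trials: the go finishing time is ex-Gaussian; times beyond the 1000 ms
    response window are misses, an extra lapse probability adds attentional
    misses, and a small probability yields a wrong-key error.  Stop trials:
    the response is inhibited iff SSD + SSRT precedes the go finishing time
    (or no go response would have occurred); staircases update after every
    stop trial and persist across blocks and runs.
    """
    cfg = config or TaskConfig()
    rng = np.random.default_rng(seed)
    trials = generate_trial_sequence(cfg, seed=int(rng.integers(2**31 - 1)))
    staircases = {
        "A": StaircaseState("A", cfg.staircase_starts_ms[0]),
        "B": StaircaseState("B", cfg.staircase_starts_ms[1]),
    }
    for rec in trials:
        t_go = float(sample_ex_gaussian(rng, params.go_mu, params.go_sigma,
                                        params.go_tau))
        lapse = rng.uniform() < params.go_miss_rate
        responded = (not lapse) and (t_go <= cfg.go_stim_ms)
        if rec.trial_type == GO:
            if not responded:
                rec.outcome = GO_MISS
                rec.response = None
            elif rng.uniform() < params.go_error_rate:
                rec.outcome = GO_ERROR
                rec.response = "left"  # wrong key
                rec.rt_ms = t_go
            else:
                rec.outcome = GO_CORRECT
                rec.response = "right"
                rec.rt_ms = t_go
        else:
            state = staircases[rec.staircase_id]
            rec.ssd_ms = state.current_ssd
            t_stop = rec.ssd_ms + params.true_ssrt
            if cfg.ssrt_jitter_sd_ms > 0:
                t_stop += rng.normal(0.0, cfg.ssrt_jitter_sd_ms)
            if (not responded) or t_stop < t_go:
                rec.outcome = STOP_SUCCESS
                rec.response = None
            else:
                rec.outcome = STOP_FAIL
                rec.response = "right"
                rec.rt_ms = t_go
            staircases[rec.staircase_id] = staircase_update(
                state, rec.outcome, cfg.staircase_step_ms, cfg.go_stim_ms)
    last_by_run = {}
    for rec in trials:
        last_by_run[rec.run] = rec.onset_ms + cfg.go_stim_ms + rec.null_after_ms
    return SessionLog(subject_id=params.subject_id, trials=trials, config=cfg,
                      run_duration_ms=max(last_by_run.values()) if last_by_run else 0.0)


def split_runs(log: SessionLog) -> list[SessionLog]:
    """Per-run sub-logs (onsets are already run-relative)."""
    runs = sorted({t.run for t in log.trials})
    return [SessionLog(subject_id=log.subject_id,
                       trials=[t for t in log.trials if t.run == r],
                       config=log.config,
                       run_duration_ms=log.run_duration_ms)
            for r in runs]
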