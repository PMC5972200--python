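"""Repeated k-fold cross-validation test of brain-behaviour prediction
reliability.

Subjects are repeatedly partitioned into k near-equal folds; for each fold a
univariate linear regression of SSRT on activation is fit on the remaining
folds and evaluated as the Pearson correlation between predicted and
observed SSRT on the held-out fold.  The k fold correlations are averaged,
the partitioning is repeated ``n_iter`` times, and the prediction is called
reliable when at least ``criterion`` (default 95%) of the ``n_iter``
fold-averaged correlations exceed zero.

Note the orientation: the evaluation correlates *predictions* with observed
values, so a strong negative activation-SSRT coupling yields positive values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CVConfig:
    k: int = 3
    n_iter: int = 1000
    criterion: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not (0.0 < self.criterion < 1.0):
            raise ValueError("criterion must lie in (0, 1)")


@dataclass
class CVResult:
    mean_r_distribution: np.ndarray
    prop_positive: float
    grand_mean_r: float
    reliable: bool
    config: CVConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"iteration": np.arange(self.mean_r_distribution.size),
                             "mean_r": self.mean_r_distribution})

    def summary(self) -> dict:
        return {"n_iter": int(self.mean_r_distribution.size),
                "prop_positive": float(self.prop_positive),
                "grand_mean_r": float(self.grand_mean_r),
                "reliable": bool(self.reliable)}


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(((a - a.mean()) @ (b - b.mean())) / (a.size * sa * sb))


def cv_mean_r(x, y, k: int = 3, rng: np.random.Generator | None = None,
              seed: int | None = None) -> float:
    """One repetition: mean over k folds of Pearson(predicted, observed).

    Folds are a random near-equal partition (sizes differ by at most 1).
    A fold whose correlation is undefined (constant predictions or constant
    held-out y) contributes 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must be aligned")
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} subjects for {k} folds")
    if rng is None:
        rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    rs = []
    for i, test_idx in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        x_tr, y_tr = x[train_idx], y[train_idx]
        if x_tr.std() == 0:
            warnings.warn("constant activation in a training fold; "
                          "fold correlation set to 0", stacklevel=2)
            rs.append(0.0)
            continue
        slope, intercept = np.polyfit(x_tr, y_tr, 1)
        pred = slope * x[test_idx] + intercept
        r = _pearson(pred, y[test_idx])
        if np.isnan(r):
            warnings.warn("undefined fold correlation (constant predictions "
                          "or outcomes); fold contributes 0", stacklevel=2)
            r = 0.0
        rs.append(r)
    return float(np.mean(rs))


def run_cv_reliability(x, y, config: CVConfig | None = None) -> CVResult:
    """``n_iter`` independent repartitions of :func:`cv_mean_r`."""
    cfg = config or CVConfig()
    rng = np.random.default_rng(cfg.seed)
    dist = np.array([cv_mean_r(x, y, k=cfg.k, rng=rng)
                     for _ in range(cfg.n_iter)])
    prop = float(np.mean(dist > 0))
    return CVResult(mean_r_distribution=dist, prop_positive=prop,
                    grand_mean_r=float(dist.mean()),
                    reliable=prop >= cfg.criterion, config=cfg)
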