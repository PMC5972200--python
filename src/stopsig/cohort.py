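"""Synthetic cohort generation for a stop-signal inhibition study.

Subjects carry a latent ex-Gaussian go-RT process, a true stop-signal
reaction time (SSRT), lapse/error rates, and clinical metadata.  Group-level
structure is injected through a configurable correlation between each
subject's inhibition-related activation (a scalar "beta") and their SSRT:
strongly negative in controls, near zero in patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PATIENT = "patient"
CONTROL = "control"

#: Post-hoc activation-SSRT couplings used as generative defaults.
DEFAULT_COUPLING_CONTROL = -0.537
DEFAULT_COUPLING_PATIENT = 0.089


@dataclass(frozen=True)
class SubjectParams:
    """Latent generative parameters for one subject.

    ``go_mu``/``go_sigma``/``go_tau`` parameterise the ex-Gaussian go-RT
    distribution (ms); ``true_ssrt`` is the latency of the covert stop
    process raced against the go process.
    """

    subject_id: str
    group: str
    age: float
    go_mu: float = 450.0
    go_sigma: float = 60.0
    go_tau: float = 100.0
    true_ssrt: float = 250.0
    go_error_rate: float = 0.01
    go_miss_rate: float = 0.01
    activation_noise_sd: float = 1.0
    ielt_min: float = float("nan")
    pedt: float = float("nan")

    def __post_init__(self) -> None:
        if self.group not in (PATIENT, CONTROL):
            raise ValueError(f"unknown group label: {self.group!r}")
        if self.go_sigma <= 0:
            raise ValueError("go_sigma must be > 0")
        if self.go_tau < 0:
            raise ValueError("go_tau must be >= 0")
        if self.true_ssrt <= 0:
            raise ValueError("true_ssrt must be > 0")
        for name in ("go_error_rate", "go_miss_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")


@dataclass(frozen=True)
class CohortConfig:
    """Population distributions the cohort is drawn from.

    Central values are chosen so that simulated behavioural summaries land
    near typical group means for this task (correct-go RT ~550 ms, SSRT
    ~250-280 ms, mean SSD ~260 ms).  Ages are uniform on the groups'
    observed ranges; clinical scores are group-separated Gaussians carried
    as metadata only.
    """

    go_mu_mean: float = 450.0
    go_mu_sd: float = 80.0
    go_sigma_mean: float = 60.0
    go_sigma_sd: float = 10.0
    go_tau_mean: float = 100.0
    go_tau_sd: float = 30.0
    ssrt_mean: float = 250.0
    ssrt_sd: float = 30.0
    go_error_rate: float = 0.01
    go_miss_rate: float = 0.01
    age_range_patient: tuple[float, float] = (21.0, 45.0)
    age_range_control: tuple[float, float] = (24.0, 37.0)
    ielt_patient: tuple[float, float] = (0.62, 0.28)
    ielt_control: tuple[float, float] = (10.73, 6.10)
    pedt_patient: tuple[float, float] = (17.50, 1.96)
    pedt_control: tuple[float, float] = (0.80, 1.40)
    coupling_control: float = DEFAULT_COUPLING_CONTROL
    coupling_patient: float = DEFAULT_COUPLING_PATIENT
    activation_noise_sd: float = 1.0


@dataclass(frozen=True)
class Cohort:
    subjects: tuple[SubjectParams, ...]
    coupling_control: float
    coupling_patient: float
    seed: int

    def __post_init__(self) -> None:
        for c in (self.coupling_control, self.coupling_patient):
            if not (-1.0 < c < 1.0):
                raise ValueError("couplings must lie in (-1, 1)")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.subjects])


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, size: int | None = None) -> np.ndarray:
    """Resampling-based lower-truncated normal (truncation mild at defaults)."""
    out = rng.normal(mean, sd, size=size)
    arr = np.atleast_1d(out).astype(float)
    bad = arr <= low
    while bad.any():
        arr[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = arr <= low
    return arr if size is not None else float(arr[0])


def sample_cohort(n_patients: int = 38, n_controls: int = 30,
                  config: CohortConfig | None = None,
                  seed: int = 0) -> Cohort:
    """Draw a synthetic cohort. Deterministic for a fixed seed.

    Patients are listed first, then controls.
    """
    if n_patients < 0 or n_controls < 0:
        raise ValueError("group sizes must be non-negative")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    subjects: list[SubjectParams] = []
    for group, n in ((PATIENT, n_patients), (CONTROL, n_controls)):
        age_lo, age_hi = (cfg.age_range_patient if group == PATIENT
                          else cfg.age_range_control)
        ielt_m, ielt_s = cfg.ielt_patient if group == PATIENT else cfg.ielt_control
        pedt_m, pedt_s = cfg.pedt_patient if group == PATIENT else cfg.pedt_control
        for i in range(n):
            subjects.append(SubjectParams(
                subject_id=f"sub-{group[:3]}{i + 1:03d}",
                group=group,
                age=float(rng.uniform(age_lo, age_hi)),
                go_mu=_truncated_normal(rng, cfg.go_mu_mean, cfg.go_mu_sd, 150.0),
                go_sigma=_truncated_normal(rng, cfg.go_sigma_mean, cfg.go_sigma_sd, 5.0),
                go_tau=_truncated_normal(rng, cfg.go_tau_mean, cfg.go_tau_sd, 1.0),
                true_ssrt=_truncated_normal(rng, cfg.ssrt_mean, cfg.ssrt_sd, 50.0),
                go_error_rate=cfg.go_error_rate,
                go_miss_rate=cfg.go_miss_rate,
                activation_noise_sd=cfg.activation_noise_sd,
                ielt_min=max(0.05, float(rng.normal(ielt_m, ielt_s))),
                pedt=max(0.0, float(rng.normal(pedt_m, pedt_s))),
            ))
    return Cohort(subjects=tuple(subjects),
                  coupling_control=cfg.coupling_control,
                  coupling_patient=cfg.coupling_patient,
                  seed=seed)


def sample_ex_gaussian(rng: np.random.Generator, mu: float, sigma: float,
                       tau: float, size: int | None = None) -> np.ndarray | float:
    """Ex-Gaussian draws: Normal(mu, sigma) + Exponential(tau)."""
    g = rng.normal(mu, sigma, size=size)
    if tau > 0:
        g = g + rng.exponential(tau, size=size)
    return g


def sample_coupled_activation(ssrt_values: np.ndarray, target_r: float,
                              noise_sd: float = 1.0, seed: int = 0,
                              exact: bool = False) -> np.ndarray:
    """Generate activation values correlated with SSRT at ``target_r``.

    In population mode the output has *population* correlation ``target_r``
    with the input.  With ``exact=True`` the noise component is
    orthogonalised against the (standardised) SSRT so the *empirical*
    Pearson correlation equals ``target_r`` to numerical precision.

    Parameters
    ----------
    ssrt_values : array of SSRTs (ms), length >= 2 (>= 3 in exact mode).
    target_r : desired Pearson correlation, |target_r| < 1.
    noise_sd : output scale (standard deviation of the activation values).
    """
    x = np.asarray(ssrt_values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 SSRT values")
    if not (-1.0 < target_r < 1.0):
        raise ValueError("|target_r| must be < 1")
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(x.size)
    sx = x.std()
    if sx == 0:
        raise ValueError("ssrt_values are constant; correlation undefined")
    zx = (x - x.mean()) / sx
    if not exact:
        out = target_r * zx + math.sqrt(1.0 - target_r**2) * e
        return noise_sd * out
    if x.size < 3:
        raise ValueError("exact mode needs at least 3 values")
    # Orthogonalise the noise against zx, standardise both empirically.
    e = e - e.mean()
    e = e - (e @ zx) / (zx @ zx) * zx
    if np.allclose(e, 0):  # pathological draw; nudge deterministically
        e = np.roll(zx, 1) - zx
        e = e - e.mean()
        e = e - (e @ zx) / (zx @ zx) * zx
    ze = e / e.std()
    out = target_r * zx + math.sqrt(1.0 - target_r**2) * ze
    return noise_sd * out


def cohort_activation(cohort: Cohort, ssrt: np.ndarray, seed: int = 0,
                      exact: bool = False) -> np.ndarray:
    """Per-subject activation coupled to SSRT at group-specific correlations."""
    ssrt = np.asarray(ssrt, dtype=float)
    if ssrt.size != len(cohort):
        raise ValueError("ssrt length must match cohort size")
    groups = cohort.groups
    out = np.empty(len(cohort))
    for gi, (label, r) in enumerate(((PATIENT, cohort.coupling_patient),
                                     (CONTROL, cohort.coupling_control))):
        idx = np.flatnonzero(groups == label)
        if idx.size == 0:
            continue
        noise_sd = cohort.subjects[idx[0]].activation_noise_sd
        out[idx] = sample_coupled_activation(
            ssrt[idx], r, noise_sd=noise_sd, seed=seed + gi, exact=exact)
    return out


def participants_table(cohort: Cohort) -> pd.DataFrame:
    """Provenance table (one row per subject) of the generative truth."""
    rows = [{
        "subject_id": s.subject_id, "group": s.group, "age": s.age,
        "go_mu_ms": s.go_mu, "go_sigma_ms": s.go_sigma, "go_tau_ms": s.go_tau,
        "true_ssrt_ms": s.true_ssrt, "go_error_rate": s.go_error_rate,
        "go_miss_rate": s.go_miss_rate, "ielt_min": s.ielt_min, "pedt": s.pedt,
    } for s in cohort.subjects]
    return pd.DataFrame(rows)


def write_participants(path, cohort: Cohort) -> None:
    participants_table(cohort).to_csv(path, sep="\t", index=False, na_rep="n/a")
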