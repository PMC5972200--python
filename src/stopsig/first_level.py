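"""Event-related GLM: canonical HRF, design matrices, forward BOLD simulation
and per-subject contrast estimation on a small voxel grid.

Events are modelled as impulses at stimulus onset convolved with a canonical
double-gamma haemodynamic response function; each condition also gets its
temporal derivative as a covariate of no interest, and unmodelled null time
forms the implicit baseline.  The subject-level contrast of interest is
successful inhibition > successful go.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import nibabel as nib
from scipy import ndimage
from scipy.signal import lfilter
from scipy.stats import gamma as gamma_dist

from .task import (GO_CORRECT, GO_ERROR, GO_MISS, STOP_SUCCESS, STOP_FAIL,
                   SessionLog)

CONDITIONS = (GO_CORRECT, STOP_SUCCESS, STOP_FAIL, "other")

#: default contrast: successful inhibition > successful go
DEFAULT_CONTRAST = {STOP_SUCCESS: 1.0, GO_CORRECT: -1.0}


@dataclass(frozen=True)
class AcquisitionSpec:
    tr_s: float = 2.0
    task_volumes_per_run: int = 270
    rest_volumes: int = 210
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if min(self.grid_shape) < 1 or min(self.task_volumes_per_run,
                                           self.rest_volumes) < 1:
            raise ValueError("dimensions must be positive")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


@dataclass
class DesignMatrix:
    matrix: np.ndarray              # (n_volumes, n_columns)
    names: list[str]
    condition_columns: dict[str, int]
    degenerate: list[str]           # conditions with zero events
    tr_s: float

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


@dataclass
class BoldRun:
    data: np.ndarray                # (nx, ny, nz, n_volumes)
    tr_s: float

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]


@dataclass
class ContrastMap:
    values: np.ndarray              # (nx, ny, nz)
    contrast_id: str


def canonical_hrf(dt_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt_s``, unit peak amplitude.

    Response gamma peaks near 5 s, undershoot gamma near 15 s, with a 6:1
    peak-to-undershoot ratio.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    h = gamma_dist.pdf(t, a=6.0, scale=1.0) - gamma_dist.pdf(t, a=16.0, scale=1.0) / 6.0
    return h / h.max()


def _condition_of(outcome: str) -> str:
    if outcome in (GO_CORRECT, STOP_SUCCESS, STOP_FAIL):
        return outcome
    return "other"  # go errors and misses pooled as nuisance


def build_design_matrix(events: SessionLog, spec: AcquisitionSpec,
                        oversample: int = 16,
                        event_duration_s: float = 0.0) -> DesignMatrix:
    """Condition regressors (HRF-convolved impulses at onset) + temporal
    derivatives + intercept.  Conditions without events yield all-zero
    columns flagged as degenerate."""
    n_vol = spec.task_volumes_per_run
    run_dur_s = n_vol * spec.tr_s
    dt = spec.tr_s / oversample
    n_fine = n_vol * oversample
    hrf = canonical_hrf(dt)
    dhrf = np.gradient(hrf, dt)

    onsets: dict[str, list[float]] = {c: [] for c in CONDITIONS}
    for rec in events.trials:
        onset_s = rec.onset_ms / 1000.0
        if onset_s < 0 or onset_s >= run_dur_s:
            raise ValueError(
                f"trial {rec.trial_index} onset {onset_s:.3f}s outside run "
                f"[0, {run_dur_s:.3f})s")
        onsets[_condition_of(rec.outcome)].append(onset_s)

    vol_idx = np.arange(n_vol) * oversample
    cols, names, cond_cols, degenerate = [], [], {}, []
    for cond in CONDITIONS:
        stick = np.zeros(n_fine)
        for on in onsets[cond]:
            i0 = int(round(on / dt))
            if event_duration_s <= 0:
                stick[i0] += 1.0
            else:
                i1 = min(int(round((on + event_duration_s) / dt)) + 1, n_fine)
                stick[i0:i1] += 1.0
        conv = np.convolve(stick, hrf)[:n_fine]
        dconv = np.convolve(stick, dhrf)[:n_fine]
        cond_cols[cond] = len(cols)
        cols.append(conv[vol_idx])
        names.append(cond)
        cols.append(dconv[vol_idx])
        names.append(cond + "_derivative")
        if not onsets[cond]:
            degenerate.append(cond)
    cols.append(np.ones(n_vol))
    names.append("intercept")
    return DesignMatrix(matrix=np.column_stack(cols), names=names,
                        condition_columns=cond_cols, degenerate=degenerate,
                        tr_s=spec.tr_s)


def simulate_task_run(design: DesignMatrix, true_betas: dict[str, np.ndarray],
                      noise_sd: float = 1.0, seed: int = 0,
                      ar1_rho: float = 0.3) -> BoldRun:
    """Forward model: signal = condition columns x true betas, plus AR(1)
    Gaussian noise with stationary standard deviation ``noise_sd``."""
    shapes = {np.asarray(b).shape for b in true_betas.values()}
    if len(shapes) != 1:
        raise ValueError("all beta maps must share one grid shape")
    grid = shapes.pop()
    n_vol = design.n_volumes
    unknown = set(true_betas) - set(design.condition_columns)
    if unknown:
        raise ValueError(f"betas given for unknown conditions: {sorted(unknown)}")
    v = int(np.prod(grid))
    signal = np.zeros((n_vol, v))
    for cond, beta in true_betas.items():
        col = design.matrix[:, design.condition_columns[cond]]
        signal += np.outer(col, np.asarray(beta, dtype=float).ravel())
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        w = rng.standard_normal((n_vol, v))
        if ar1_rho:
            w = lfilter([1.0], [1.0, -ar1_rho], w, axis=0)
            w *= np.sqrt(1.0 - ar1_rho**2)  # stationary unit variance
        signal += noise_sd * w
    data = signal.T.reshape(grid + (n_vol,))
    return BoldRun(data=data, tr_s=design.tr_s)


def fit_glm(run: BoldRun, design: DesignMatrix) -> tuple[np.ndarray, DesignMatrix]:
    """Per-voxel OLS after pruning degenerate (all-zero) columns.

    Returns betas on the full column set (pruned columns NaN) and the design.
    """
    X = design.matrix
    keep = ~np.all(X == 0, axis=0)
    Xk = X[:, keep]
    if np.linalg.matrix_rank(Xk) < Xk.shape[1]:
        raise ValueError(
            "design matrix is rank deficient after pruning zero columns; "
            "check for duplicated or collinear regressors")
    grid = run.data.shape[:-1]
    Y = run.data.reshape(-1, run.n_volumes).T          # (T, V)
    beta_k, *_ = np.linalg.lstsq(Xk, Y, rcond=None)
    betas = np.full((X.shape[1], Y.shape[1]), np.nan)
    betas[keep] = beta_k
    return betas.reshape((X.shape[1],) + grid), design


def fit_contrast(run: BoldRun, design: DesignMatrix,
                 contrast: dict[str, float] | None = None) -> ContrastMap:
    """OLS contrast map (weighted combination of condition betas)."""
    weights = contrast or DEFAULT_CONTRAST
    unknown = set(weights) - set(design.condition_columns)
    if unknown:
        raise ValueError(f"contrast names unknown conditions: {sorted(unknown)}")
    for cond, w in weights.items():
        if w != 0 and cond in design.degenerate:
            raise ValueError(f"contrast weights degenerate condition {cond!r}")
    betas, _ = fit_glm(run, design)
    values = np.zeros(run.data.shape[:-1])
    for cond, w in weights.items():
        values = values + w * betas[design.condition_columns[cond]]
    cid = " + ".join(f"{w:+g}*{c}" for c, w in weights.items())
    return ContrastMap(values=values, contrast_id=cid)


def average_contrasts(maps: list[ContrastMap]) -> ContrastMap:
    """Across-run subject contrast: plain average of per-run maps."""
    if not maps:
        raise ValueError("no contrast maps to average")
    ids = {m.contrast_id for m in maps}
    if len(ids) != 1:
        raise ValueError("cannot average maps of different contrasts")
    return ContrastMap(values=np.mean([m.values for m in maps], axis=0),
                       contrast_id=ids.pop())


def smooth_map(values: np.ndarray, fwhm_mm: float = 6.0,
               voxel_size_mm: float = 3.0) -> np.ndarray:
    """Isotropic Gaussian smoothing; sigma = FWHM / (2*sqrt(2*ln 2))."""
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    return ndimage.gaussian_filter(values, sigma=sigma_vox)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def save_nifti(path, data: np.ndarray, voxel_size_mm: float = 3.0,
               tr_s: float | None = None) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    if tr_s is not None and data.ndim == 4:
        img.header.set_zooms((voxel_size_mm,) * 3 + (tr_s,))
    nib.save(img, str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())
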