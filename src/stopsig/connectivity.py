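"""Seed-based resting-state functional connectivity.

A synthetic resting run plants a band-limited (0.01-0.1 Hz) latent signal in
a seed region and shares it with a target region at a requested correlation,
on top of motion, CSF and white-matter confounds.  The analysis chain drops
initial volumes, linearly detrends, regresses out 12 motion regressors
(6 parameters + first differences), CSF and WM averages and one indicator
per flagged outlier volume ("scrubbing"), band-pass filters the residuals,
computes the per-voxel correlation with the mean seed time series, applies
the Fisher r-to-z transform, and compares groups voxelwise with an age
covariate and permutation cluster-level FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .first_level import AcquisitionSpec
from .group_level import (ClusterConfig, GroupStatMap, ThresholdResult,
                          cluster_fdr, voxelwise_group_model, _max_cluster_size)


@dataclass
class RestRun:
    data: np.ndarray                 # (nx, ny, nz, n_volumes)
    motion: np.ndarray               # (n_volumes, 6): 3 translations mm, 3 rotations deg
    csf: np.ndarray                  # (n_volumes,)
    wm: np.ndarray
    outlier_flags: np.ndarray        # bool (n_volumes,)
    tr_s: float

    def __post_init__(self) -> None:
        t = self.data.shape[-1]
        for name in ("motion", "csf", "wm", "outlier_flags"):
            if getattr(self, name).shape[0] != t:
                raise ValueError(f"{name} length must equal volume count")


@dataclass
class FCMap:
    r: np.ndarray
    z: np.ndarray
    valid: np.ndarray


@dataclass(frozen=True)
class ConfoundAmplitudes:
    motion: float = 0.5      # voxel-signal units per confound sd
    csf: float = 0.5
    wm: float = 0.5
    motion_scale_mm: float = 0.02  # per-volume random-walk step sd; keeps
                                   # typical cumulative motion below the 1 mm
                                   # QC bound, as in a compliant subject


def default_masks(grid_shape=(12, 12, 12)) -> tuple[np.ndarray, np.ndarray]:
    """A 2x2x2 seed block and a 3x3x3 target block on the grid."""
    seed = np.zeros(grid_shape, dtype=bool)
    target = np.zeros(grid_shape, dtype=bool)
    seed[2:4, 2:4, 2:4] = True
    lo = tuple(max(0, s - 5) for s in grid_shape)
    target[lo[0]:lo[0] + 3, lo[1]:lo[1] + 3, lo[2]:lo[2] + 3] = True
    return seed, target


def _bandlimited_noise(rng: np.random.Generator, shape, tr_s: float,
                       band=(0.01, 0.1)) -> np.ndarray:
    """Unit-variance Gaussian noise band-pass filtered along the last axis."""
    x = rng.standard_normal(shape)
    sos = _band_sos(band, tr_s)
    y = sps.sosfiltfilt(sos, x, axis=-1)
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def _band_sos(band: tuple[float, float], tr_s: float, order: int = 4):
    nyq = 0.5 / tr_s
    lo, hi = band
    return sps.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")


def simulate_rest_run(spec: AcquisitionSpec | None = None,
                      seed_target_r: float = 0.6,
                      confounds: ConfoundAmplitudes | None = None,
                      seed: int = 0,
                      seed_mask: np.ndarray | None = None,
                      target_mask: np.ndarray | None = None,
                      local_noise_sd: float = 0.3,
                      outlier_volumes: np.ndarray | None = None) -> RestRun:
    """Resting run with a planted in-band seed-target coupling.

    Seed voxels carry the latent signal plus small local noise; each target
    voxel mixes the latent with independent band-limited noise so its
    population correlation with the latent equals ``seed_target_r``.
    """
    if not (-1.0 < seed_target_r < 1.0):
        raise ValueError("|seed_target_r| must be < 1")
    spec = spec or AcquisitionSpec()
    amp = confounds or ConfoundAmplitudes()
    rng = np.random.default_rng(seed)
    grid = spec.grid_shape
    T = spec.rest_volumes
    if seed_mask is None or target_mask is None:
        dseed, dtarget = default_masks(grid)
        seed_mask = dseed if seed_mask is None else seed_mask
        target_mask = dtarget if target_mask is None else target_mask

    latent = _bandlimited_noise(rng, (T,), spec.tr_s)
    data = _bandlimited_noise(rng, grid + (T,), spec.tr_s)  # background
    data += 0.5 * rng.standard_normal(grid + (T,))           # broadband noise

    sv = np.argwhere(seed_mask)
    for v in sv:
        data[tuple(v)] = latent + local_noise_sd * _bandlimited_noise(rng, (T,), spec.tr_s)
    r = seed_target_r
    for v in np.argwhere(target_mask):
        indep = _bandlimited_noise(rng, (T,), spec.tr_s)
        data[tuple(v)] = r * latent + np.sqrt(1 - r**2) * indep

    # confounds: motion random walks (mm / deg), CSF and WM AR-ish series
    steps = rng.standard_normal((T, 6)) * amp.motion_scale_mm
    motion = np.cumsum(steps, axis=0)
    csf = _bandlimited_noise(rng, (T,), spec.tr_s, band=(0.005, 0.15))
    wm = _bandlimited_noise(rng, (T,), spec.tr_s, band=(0.005, 0.15))

    if amp.motion > 0 or amp.csf > 0 or amp.wm > 0:
        loadings = rng.standard_normal(grid + (8,))
        conf = np.concatenate([
            amp.motion * _standardize(motion),
            amp.csf * csf[:, None],
            amp.wm * wm[:, None],
        ], axis=1)                                            # (T, 8)
        data += np.einsum("xyzk,tk->xyzt", loadings, conf)

    flags = np.zeros(T, dtype=bool)
    if outlier_volumes is not None:
        flags[np.asarray(outlier_volumes, dtype=int)] = True
        data[..., flags] += rng.standard_normal((grid + (int(flags.sum()),))) * 5.0

    return RestRun(data=data, motion=motion, csf=csf, wm=wm,
                   outlier_flags=flags, tr_s=spec.tr_s)


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def motion_qc(run: RestRun, trans_limit_mm: float = 1.0,
              rot_limit_deg: float = 1.0) -> bool:
    """Pass unless any |translation| > limit (mm) or |rotation| > limit (deg);
    comparisons are strict, so values exactly at the limit pass."""
    trans = np.abs(run.motion[:, :3])
    rot = np.abs(run.motion[:, 3:])
    return not (np.any(trans > trans_limit_mm) or np.any(rot > rot_limit_deg))


def _drop_dependent_columns(C: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Keep a maximal linearly independent column subset (pivoted QR)."""
    from scipy.linalg import qr
    if C.shape[1] == 0:
        return C
    _, R, piv = qr(C, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > tol * (diag[0] if diag.size else 1.0)))
    if rank < C.shape[1]:
        warnings.warn(f"dropping {C.shape[1] - rank} linearly dependent "
                      "confound column(s)", stacklevel=2)
    return C[:, np.sort(piv[:rank])]


def regress_confounds(run: RestRun, drop_initial: int = 4
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Drop initial volumes, detrend, and regress out the confound matrix.

    Confounds: 6 motion parameters and their first differences, CSF and WM
    averages, and one indicator column per flagged outlier volume.
    Returns (residuals (T, V), confound matrix (T, k)).
    """
    T = run.data.shape[-1]
    if T - drop_initial < 20:
        raise ValueError("need at least 20 usable volumes after dropping")
    data = run.data[..., drop_initial:].astype(float)
    motion = run.motion[drop_initial:]
    csf = run.csf[drop_initial:]
    wm = run.wm[drop_initial:]
    flags = run.outlier_flags[drop_initial:]
    n = data.shape[-1]

    Y = sps.detrend(data.reshape(-1, n), axis=-1, type="linear").T  # (T, V)

    dmotion = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    conf_cols = [_standardize(motion), _standardize(dmotion),
                 _standardize(csf[:, None]), _standardize(wm[:, None])]
    if flags.any():
        onehot = np.zeros((n, int(flags.sum())))
        onehot[np.flatnonzero(flags), np.arange(int(flags.sum()))] = 1.0
        conf_cols.append(onehot)
    C = np.column_stack([np.ones(n)] + conf_cols)
    C = _drop_dependent_columns(C)
    beta, *_ = np.linalg.lstsq(C, Y, rcond=None)
    return Y - C @ beta, C


def denoise(run: RestRun, band: tuple[float, float] = (0.01, 0.1),
            drop_initial: int = 4) -> np.ndarray:
    """Detrend -> confound regression -> band-pass, in that order.

    Returns the cleaned (nx, ny, nz, T - drop_initial) array.
    """
    Y, _ = regress_confounds(run, drop_initial)
    sos = _band_sos(band, run.tr_s)
    Y = sps.sosfiltfilt(sos, Y, axis=0)
    n = Y.shape[0]
    return Y.T.reshape(run.data.shape[:-1] + (n,))


def seed_fc_map(cleaned: np.ndarray, seed_mask: np.ndarray) -> FCMap:
    """Per-voxel Pearson r with the mean seed time series, Fisher z-mapped.

    |r| = 1 is clipped to 1 - 1e-7 before atanh; zero-variance voxels are
    masked out (z undefined).
    """
    if not np.any(seed_mask):
        raise ValueError("seed mask is empty")
    grid = cleaned.shape[:-1]
    T = cleaned.shape[-1]
    ts = cleaned.reshape(-1, T)
    seed_ts = ts[seed_mask.ravel()].mean(axis=0)
    ss = seed_ts.std()
    if ss == 0:
        raise ValueError("seed time series has zero variance")
    vs = ts.std(axis=1)
    valid = vs > 0
    zc = (seed_ts - seed_ts.mean()) / ss
    r = np.full(ts.shape[0], np.nan)
    r[valid] = (ts[valid] - ts[valid].mean(axis=1, keepdims=True)) @ zc / (T * vs[valid])
    r_clip = np.clip(r, -(1 - 1e-7), 1 - 1e-7)
    z = np.arctanh(r_clip)
    z[~valid] = np.nan
    return FCMap(r=r.reshape(grid), z=z.reshape(grid), valid=valid.reshape(grid))


def group_fc_difference(z_maps: np.ndarray, group, age,
                        cluster_cfg: ClusterConfig | None = None
                        ) -> tuple[GroupStatMap, ThresholdResult]:
    """Two-sample voxelwise model on Fisher-z maps with age covariate and
    permutation cluster-level FDR (shared machinery with the task analysis)."""
    cfg = cluster_cfg or ClusterConfig()
    z_maps = np.asarray(z_maps, dtype=float)
    stat = voxelwise_group_model(z_maps, group=group, age=age, mode="two_sample")
    rng = np.random.default_rng(cfg.seed)
    g = np.asarray(group)
    null_max = np.empty(cfg.n_perm, dtype=int)
    for b in range(cfg.n_perm):
        gp = rng.permutation(g)
        sp = voxelwise_group_model(z_maps, group=gp, age=age, mode="two_sample")
        null_max[b] = _max_cluster_size(sp.p, cfg.forming_p)
    thr = cluster_fdr(stat.p, null_max, cfg)
    return stat, thr
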