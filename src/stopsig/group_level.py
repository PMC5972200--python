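"""Group-level voxelwise statistics.

One- and two-sample voxelwise models with an age covariate, BH-FDR
voxel thresholding, the group x activation interaction scan predicting SSRT
with permutation-based cluster-level FDR, and post-hoc per-group Pearson
correlations.

Cluster-level inference: voxelwise cluster-forming threshold (two-sided
p < 0.001 by default), 26-connected components, each observed cluster scored
against the permutation null distribution of the maximum cluster extent
(group labels shuffled), and the resulting cluster p values passed through
Benjamini-Hochberg at the cluster alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .cohort import PATIENT, CONTROL


@dataclass
class GroupStatMap:
    t: np.ndarray               # (grid)
    p: np.ndarray
    effect: np.ndarray
    model: str
    covariates: tuple[str, ...] = ()
    valid: np.ndarray | None = None   # voxels where the model was estimable


@dataclass
class ClusterConfig:
    forming_p: float = 0.001
    cluster_alpha: float = 0.05
    n_perm: int = 1000
    seed: int = 0


@dataclass
class ThresholdResult:
    mask: np.ndarray                      # surviving voxels (bool grid)
    clusters: list[dict]                  # id, size, voxels, peak, p
    procedure: str

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"cluster_id": c["id"], "size": c["size"], "peak": c["peak"],
             "cluster_p": c["p"], "survives": c["survives"]}
            for c in self.clusters])


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _encode_groups(group) -> np.ndarray:
    g = np.asarray(group)
    labels = set(np.unique(g))
    if labels == {PATIENT, CONTROL}:
        return (g == PATIENT).astype(float)
    if g.dtype.kind in "biuf" and labels <= {0, 1, 0.0, 1.0}:
        return g.astype(float)
    raise ValueError(f"need exactly two groups (patient/control or 0/1), got {labels}")


def voxelwise_group_model(maps: np.ndarray, group=None, age=None,
                          mode: str = "one_sample") -> GroupStatMap:
    """Per-voxel linear model of contrast values with centred age.

    ``maps``: (n_subjects, *grid). one_sample tests the intercept;
    two_sample tests the group indicator (patient - control).
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    grid = maps.shape[1:]
    cols = [np.ones(n)]
    names = ["intercept"]
    if mode == "two_sample":
        if group is None:
            raise ValueError("two_sample mode requires group labels")
        g = _encode_groups(group)
        for val in (0.0, 1.0):
            if (g == val).sum() < 3:
                raise ValueError("need at least 3 subjects per group")
        cols.append(g)
        names.append("group")
        test_col = 1
    elif mode == "one_sample":
        if n < 3:
            raise ValueError("need at least 3 subjects")
        test_col = 0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    covs = []
    if age is not None:
        a = np.asarray(age, dtype=float)
        cols.append(a - a.mean())
        names.append("age")
        covs.append("age")
    X = np.column_stack(cols)
    t, p, eff, valid = _ols_t(X, maps.reshape(n, -1), test_col)
    return GroupStatMap(t=t.reshape(grid), p=p.reshape(grid),
                        effect=eff.reshape(grid), model=mode,
                        covariates=tuple(covs), valid=valid.reshape(grid))


def _ols_t(X: np.ndarray, Y: np.ndarray, j: int):
    """OLS with shared design: t, two-sided p and effect for column j."""
    n, k = X.shape
    if n <= k:
        raise ValueError("more regressors than observations")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / (n - k)
    var_j = sigma2 * XtX_inv[j, j]
    valid = var_j > 0
    t = np.full(Y.shape[1], np.nan)
    t[valid] = beta[j, valid] / np.sqrt(var_j[valid])
    p = np.full(Y.shape[1], np.nan)
    p[valid] = 2.0 * stats.t.sf(np.abs(t[valid]), df=n - k)
    return t, p, beta[j], valid


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    flat = p.ravel()
    ok = ~np.isnan(flat)
    reject = np.zeros(flat.size, dtype=bool)
    if ok.any():
        reject[ok] = multipletests(flat[ok], alpha=q, method="fdr_bh")[0]
    return reject.reshape(p.shape)


def label_clusters(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """26-connected components of a boolean 3D mask."""
    return ndimage.label(mask, structure=_STRUCT26)


def _max_cluster_size(p_map: np.ndarray, forming_p: float) -> int:
    labels, n = label_clusters(np.nan_to_num(p_map, nan=1.0) < forming_p)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


# ---------------------------------------------------------------------------
# Interaction scan: SSRT ~ activation * group + age, per voxel
# ---------------------------------------------------------------------------

def _interaction_tp(act: np.ndarray, y: np.ndarray, g: np.ndarray,
                    age_c: np.ndarray):
    """Batched per-voxel OLS of y on [1, act, g, act*g, age]; returns the
    interaction t, two-sided p, and a validity mask (act: (V, n))."""
    V, n = act.shape
    k = 5
    X = np.empty((V, n, k))
    X[:, :, 0] = 1.0
    X[:, :, 1] = act
    X[:, :, 2] = g
    X[:, :, 3] = act * g
    X[:, :, 4] = age_c
    valid = act.std(axis=1) > 1e-12
    # per-group activation must vary for the interaction column to be estimable
    for val in (0.0, 1.0):
        sel = g == val
        valid &= act[:, sel].std(axis=1) > 1e-12
    t = np.full(V, np.nan)
    p = np.full(V, np.nan)
    if not valid.any():
        return t, p, valid
    Xv = X[valid]
    XtX = np.einsum("vnp,vnq->vpq", Xv, Xv)
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        XtX_inv = np.linalg.pinv(XtX)
    Xty = np.einsum("vnp,n->vp", Xv, y)
    beta = np.einsum("vpq,vq->vp", XtX_inv, Xty)
    rss = (y @ y) - np.einsum("vp,vp->v", beta, Xty)
    sigma2 = np.maximum(rss, 0.0) / (n - k)
    var = sigma2 * XtX_inv[:, 3, 3]
    good = np.isfinite(var) & (var > 0)
    tv = np.full(Xv.shape[0], np.nan)
    tv[good] = beta[good, 3] / np.sqrt(var[good])
    pv = np.full(Xv.shape[0], np.nan)
    pv[good] = 2.0 * stats.t.sf(np.abs(tv[good]), df=n - k)
    t[valid] = tv
    p[valid] = pv
    sub = np.flatnonzero(valid)
    valid[sub[~good]] = False
    return t, p, valid


def interaction_scan(maps: np.ndarray, ssrt, group, age,
                     cluster_cfg: ClusterConfig | None = None
                     ) -> tuple[GroupStatMap, ThresholdResult]:
    """Voxelwise group x activation interaction predicting SSRT.

    Main effects of activation and group and a centred-age covariate are
    always included.  Voxels with (within-group) zero-variance activation
    are flagged degenerate and excluded from the map.
    """
    cfg = cluster_cfg or ClusterConfig()
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    grid = maps.shape[1:]
    y = np.asarray(ssrt, dtype=float)
    g = _encode_groups(group)
    a = np.asarray(age, dtype=float)
    if not (y.size == g.size == a.size == n):
        raise ValueError("maps, ssrt, group and age must be aligned by subject")
    age_c = a - a.mean()
    act = maps.reshape(n, -1).T                      # (V, n)
    t, p, valid = _interaction_tp(act, y, g, age_c)
    stat = GroupStatMap(t=t.reshape(grid), p=p.reshape(grid),
                        effect=t.reshape(grid), model="interaction",
                        covariates=("age",), valid=valid.reshape(grid))

    rng = np.random.default_rng(cfg.seed)
    null_max = np.empty(cfg.n_perm, dtype=int)
    for b in range(cfg.n_perm):
        gp = rng.permutation(g)
        _, pp, _ = _interaction_tp(act, y, gp, age_c)
        null_max[b] = _max_cluster_size(pp.reshape(grid), cfg.forming_p)
    thr = cluster_fdr(stat.p, null_max, cfg)
    return stat, thr


def cluster_fdr(p_map: np.ndarray, null_max_sizes: np.ndarray,
                cfg: ClusterConfig) -> ThresholdResult:
    """Cluster-forming threshold + permutation cluster p + BH across clusters."""
    forming = np.nan_to_num(p_map, nan=1.0) < cfg.forming_p
    labels, n_clust = label_clusters(forming)
    clusters = []
    B = len(null_max_sizes)
    for cid in range(1, n_clust + 1):
        vox = np.argwhere(labels == cid)
        size = len(vox)
        p_c = (1.0 + np.sum(null_max_sizes >= size)) / (B + 1.0)
        clusters.append({"id": cid, "size": size,
                         "voxels": [tuple(v) for v in vox],
                         "peak": tuple(vox[np.argmin([p_map[tuple(v)] for v in vox])]),
                         "p": p_c})
    mask = np.zeros(p_map.shape, dtype=bool)
    if clusters:
        rej = bh_fdr(np.array([c["p"] for c in clusters]), q=cfg.cluster_alpha)
        for c, r in zip(clusters, rej):
            c["survives"] = bool(r)
            if r:
                for v in c["voxels"]:
                    mask[v] = True
    return ThresholdResult(mask=mask, clusters=clusters,
                           procedure=f"forming p<{cfg.forming_p}, "
                                     f"permutation cluster FDR q<{cfg.cluster_alpha} "
                                     f"({B} permutations)")


def posthoc_pearson(activation, ssrt, group) -> dict[str, tuple[float, float]]:
    """Per-group Pearson r (two-sided p) of mean activation vs SSRT."""
    act = np.asarray(activation, dtype=float)
    y = np.asarray(ssrt, dtype=float)
    g = np.asarray(group)
    out = {}
    for label in np.unique(g):
        sel = g == label
        if sel.sum() < 3:
            raise ValueError(f"need at least 3 subjects in group {label!r}")
        xa, ya = act[sel], y[sel]
        if xa.std() == 0 or ya.std() == 0:
            raise ValueError(f"constant input in group {label!r}")
        r, p = stats.pearsonr(xa, ya)
        out[str(label)] = (float(r), float(p))
    return out
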