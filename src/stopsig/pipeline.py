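"""End-to-end synthetic study: cohort -> task -> behaviour -> first-level GLM
-> group maps -> interaction scan -> post-hoc correlations -> CV reliability
-> resting-state FC group comparison.

Every stage draws its randomness from a sub-seed derived from the master
seed and the stage name, so outputs are reproducible and stage-local.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import behavior, cohort as cohort_mod, connectivity, cv as cv_mod
from . import events_io, first_level, group_level, task as task_mod
from .config import StudyConfig

log = logging.getLogger("stopsig")


def _planted_block(grid_shape) -> np.ndarray:
    """3x3x3 activation block where the coupling effect lives."""
    mask = np.zeros(grid_shape, dtype=bool)
    c = tuple(s // 2 for s in grid_shape)
    mask[c[0] - 1:c[0] + 2, c[1] - 1:c[1] + 2, c[2] - 1:c[2] + 2] = True
    return mask


def make_activation_maps(activation: np.ndarray, grid_shape,
                         block: np.ndarray | None = None,
                         voxel_noise_sd: float = 0.5,
                         seed: int = 0) -> np.ndarray:
    """Subject contrast-like maps: the scalar activation planted on a block
    plus independent voxel noise everywhere."""
    rng = np.random.default_rng(seed)
    n = activation.size
    block = _planted_block(grid_shape) if block is None else block
    maps = voxel_noise_sd * rng.standard_normal((n,) + tuple(grid_shape))
    maps[:, block] += activation[:, None]
    return maps


def run_pipeline(config: StudyConfig | None = None) -> dict:
    """Run the full synthetic study; returns (and writes) the summary dict."""
    cfg = config or StudyConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"master_seed": cfg.master_seed}
    t0 = time.time()

    def stage(name):
        log.info("stage %-14s +%6.1fs", name, time.time() - t0)

    # --- cohort --------------------------------------------------------
    stage("cohort")
    coh = cohort_mod.sample_cohort(cfg.n_patients, cfg.n_controls,
                                   cfg.cohort, seed=cfg.seed_for("cohort"))
    cohort_mod.write_participants(out / "participants.tsv", coh)
    summary["n_subjects"] = len(coh)

    # --- task simulation + behaviour -----------------------------------
    stage("behavior")
    summaries = []
    logs = []
    for i, subj in enumerate(coh.subjects):
        slog = task_mod.simulate_session(subj, cfg.task,
                                         seed=cfg.seed_for("task", i))
        logs.append(slog)
        summaries.append(behavior.summarize_performance(slog))
    if logs:
        events_io.write_events(out / f"{logs[0].subject_id}_events.tsv", logs[0])
    table = behavior.cohort_summary_table(summaries)
    table.insert(1, "group", coh.groups)
    table.to_csv(out / "behavior_summary.csv", index=False)
    qc_ok = table["qc_pass"].to_numpy(dtype=bool)
    summary["behavior"] = {
        "stop_success_grand_mean": float(table["stop_success_frac"].mean()),
        "mean_ssrt_ms": float(table["ssrt_ms"].mean()),
        "mean_correct_go_rt_ms": float(table["correct_go_rt_ms"].mean()),
        "n_qc_excluded": int((~qc_ok).sum()),
    }

    # QC-passing subjects drive all brain-behaviour stages
    keep = np.flatnonzero(qc_ok)
    groups = coh.groups[keep]
    ages = coh.ages[keep]
    ssrt = table["ssrt_ms"].to_numpy()[keep]

    # --- subject activation coupled to SSRT ----------------------------
    stage("activation")
    sub_cohort = cohort_mod.Cohort(
        subjects=tuple(coh.subjects[i] for i in keep),
        coupling_control=coh.coupling_control,
        coupling_patient=coh.coupling_patient, seed=coh.seed)
    activation = cohort_mod.cohort_activation(
        sub_cohort, ssrt, seed=cfg.seed_for("activation"))

    # --- first-level GLM on forward-simulated BOLD ---------------------
    stage("first_level")
    spec = cfg.acquisition
    block = _planted_block(spec.grid_shape)
    contrast_maps = np.empty((keep.size,) + spec.grid_shape)
    for j, i in enumerate(keep):
        per_run = []
        for r, run_log in enumerate(task_mod.split_runs(logs[i])):
            design = first_level.build_design_matrix(run_log, spec)
            betas = {
                task_mod.GO_CORRECT: np.ones(spec.grid_shape),
                task_mod.STOP_SUCCESS: np.ones(spec.grid_shape)
                + block * (cfg.contrast_mean + activation[j]),
            }
            run = first_level.simulate_task_run(
                design, betas, noise_sd=cfg.task_noise_sd,
                seed=cfg.seed_for("bold", int(i) * 10 + r))
            per_run.append(first_level.fit_contrast(run, design))
        contrast_maps[j] = first_level.average_contrasts(per_run).values
    first_level.save_nifti(out / "contrast_stop_gt_go.nii",
                           np.moveaxis(contrast_maps, 0, -1),
                           spec.voxel_size_mm)

    # --- group maps -----------------------------------------------------
    stage("group_level")
    if len(set(groups)) < 2:
        raise RuntimeError("group comparison requires both groups after QC; "
                           "got only " + (groups[0] if groups.size else "none"))
    one_sample = group_level.voxelwise_group_model(contrast_maps, age=ages,
                                                   mode="one_sample")
    fdr_mask = group_level.bh_fdr(one_sample.p, q=0.05)
    two_sample = group_level.voxelwise_group_model(contrast_maps, group=groups,
                                                   age=ages, mode="two_sample")
    summary["group_level"] = {
        "one_sample_fdr_voxels": int(fdr_mask.sum()),
        "two_sample_min_p": float(np.nanmin(two_sample.p)),
    }

    # --- interaction scan + post hoc ------------------------------------
    stage("interaction")
    stat, thr = group_level.interaction_scan(contrast_maps, ssrt, groups,
                                             ages, cfg.cluster)
    thr.table().to_csv(out / "interaction_clusters.csv", index=False)
    roi = thr.mask if thr.mask.any() else block
    mean_beta = contrast_maps[:, roi].mean(axis=1)
    posthoc = group_level.posthoc_pearson(mean_beta, ssrt, groups)
    summary["interaction"] = {
        "n_clusters": len(thr.clusters),
        "n_surviving": int(sum(c["survives"] for c in thr.clusters)),
        "roi_is_surviving_mask": bool(thr.mask.any()),
        "posthoc_r": {k: v[0] for k, v in posthoc.items()},
        "posthoc_p": {k: v[1] for k, v in posthoc.items()},
    }

    # --- CV reliability per group ---------------------------------------
    stage("cv")
    cv_out = {}
    for label in (cohort_mod.CONTROL, cohort_mod.PATIENT):
        sel = groups == label
        res = cv_mod.run_cv_reliability(
            mean_beta[sel], ssrt[sel],
            cv_mod.CVConfig(k=cfg.cv.k, n_iter=cfg.cv.n_iter,
                            criterion=cfg.cv.criterion,
                            seed=cfg.seed_for("cv_" + label)))
        res.to_frame().to_csv(out / f"cv_{label}.csv", index=False)
        cv_out[label] = res.summary()
    summary["cv"] = cv_out

    # --- resting-state FC ------------------------------------------------
    stage("rest_fc")
    seed_mask, target_mask = connectivity.default_masks(spec.grid_shape)
    z_maps = np.empty((keep.size,) + spec.grid_shape)
    for j, i in enumerate(keep):
        r = (cfg.fc_coupling_patient if groups[j] == cohort_mod.PATIENT
             else cfg.fc_coupling_control)
        run = connectivity.simulate_rest_run(
            spec, seed_target_r=r, confounds=cfg.confounds,
            seed=cfg.seed_for("rest", int(i)),
            seed_mask=seed_mask, target_mask=target_mask)
        cleaned = connectivity.denoise(run, band=cfg.band_hz,
                                       drop_initial=cfg.drop_initial_volumes)
        z_maps[j] = connectivity.seed_fc_map(cleaned, seed_mask).z
    fc_stat, fc_thr = connectivity.group_fc_difference(z_maps, groups, ages,
                                                       cfg.cluster)
    fc_thr.table().to_csv(out / "fc_clusters.csv", index=False)
    hit = fc_thr.mask[target_mask].any()
    summary["rest_fc"] = {
        "n_surviving_clusters": int(sum(c["survives"] for c in fc_thr.clusters)),
        "target_recovered": bool(hit),
        "mean_z_control": float(z_maps[groups == cohort_mod.CONTROL][:, target_mask].mean()),
        "mean_z_patient": float(z_maps[groups == cohort_mod.PATIENT][:, target_mask].mean()),
    }

    stage("done")
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
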