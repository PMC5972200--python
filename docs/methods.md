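# Methods

This note documents the generative models, estimators and numerical choices
behind `stopsig`, and what the synthetic experiments do and do not show.

## Task and race model

The task engine reproduces the stop-signal design: two runs of two blocks,
each with 36 go and 12 stop trials shuffled together (25% stop), a 1000 ms
go stimulus, and inter-trial null events. The published design states the
null-event family (exponential), range (0.5–4 s) and mean (1 s) but not the
truncation convention; we draw from an exponential truncated to
[0.5, 4] s whose rate is solved (Brent root-finding on the closed-form
truncated mean) so the *truncated* mean is exactly 1 s.

Stop-signal delays come from two independent one-up/one-down staircases
starting at 250 and 350 ms with 50 ms steps. Each block's 12 stop trials are
split 6/6 over the staircases in shuffled order; staircase state persists
across blocks and runs. SSDs are clamped to [0, 1000 ms] — the design is
silent on bounds, and an SSD beyond the response window is meaningless.

Behaviour follows the independent horse-race model. Go finishing times are
ex-Gaussian (defaults mu = 450 ms, sigma = 60 ms, tau = 100 ms, chosen so
that simulated summaries land near the published group means: correct-go RT
~550 ms, SSRT ~250 ms, mean SSD ~260–290 ms; the study reports only summary
statistics, not a generative model). The stop process is deterministic at
the subject's true SSRT (default 250 ms); a configurable Gaussian jitter
(default 0) is available and does not move the estimator's target, which is
the mean. A stop trial is inhibited iff SSD + SSRT < T_go, or if no go
response would have occurred at all (T_go beyond the 1000 ms window, or an
attentional lapse) — this keeps the invariant that a successful stop is
exactly a stop trial without a response. Lapse and wrong-key probabilities
(1% each) produce the ~1% miss/error rates in the published table.

## SSRT estimation and QC

The quantile method: correct-go RTs sorted ascending; the quantile RT is the
element at 1-based rank ceil(p·n) where p is the proportion of failed
inhibitions pooled over all stop trials; SSRT = quantile RT − mean SSD over
all stop trials. The rank rule uses no interpolation (the classical method
predates interpolated quantiles); rank 0 maps to rank 1 and a small epsilon
guards float fuzz at integer ranks. The five exclusion rules are applied as
strict inequalities exactly as printed, so boundary values (25%, 75%, 60%,
10%, 20%, 50 ms) pass.

At 1000 stop trials per subject the estimator recovers the generative
250 ms within a few ms (small negative bias ~5–8 ms from pre-convergence
staircase samples entering the mean SSD); at the real design's 48 stop
trials per-subject estimates scatter by tens of ms but group means remain
near truth.

## First-level GLM

The canonical HRF is a double-gamma (response gamma shape 6, undershoot
shape 16, 6:1 ratio, unit peak, ~5 s peak). Events are zero-duration
impulses at stimulus onset on a 16x-oversampled grid, convolved and sampled
at the 2 s TR; each of four conditions (correct go, successful stop, failed
stop, other = go errors/misses) gets a regressor plus its temporal
derivative, with an intercept — failed stops and error/miss trials are
modelled as nuisance conditions, standard practice where the published
model describes only the two successful event types. Conditions without
events yield all-zero columns, flagged degenerate and pruned before the
per-voxel OLS fit; a rank-deficient pruned design is an error. Forward
simulation adds AR(1) Gaussian noise (rho = 0.3 by default); estimation
remains plain OLS (no prewhitening), so contrast estimates are unbiased
with slightly mis-calibrated single-subject variances — group stages
re-estimate variance across subjects. Two-run subjects average per-run
contrast maps; averaging commutes with the noiseless forward model.
Optional isotropic Gaussian smoothing uses sigma = FWHM/(2*sqrt(2 ln 2))
with 3 mm voxels (6 mm FWHM analogue).

## Group statistics

Voxelwise one-/two-sample models regress contrast values on an intercept
(+ group indicator) and centred age, with t/p from OLS. Voxel-level FDR is
Benjamini–Hochberg (statsmodels). The interaction scan fits, per voxel,
SSRT ~ activation + group + activation x group + age (main effects always
included under the hierarchy principle) in a batched normal-equations OLS;
voxels with zero within-group activation variance are excluded as
degenerate. Cluster-level inference replaces the original random-field
cluster FDR, which is not reproducible outside SPM internals, with a
permutation scheme of identical error-control intent: cluster-forming
two-sided p < 0.001, 26-connected components, each observed cluster's p
computed against the permutation (group-label shuffle) null of the maximum
cluster extent with the (1 + #{exceed})/(B + 1) estimator, then BH across
clusters at q = 0.05. Default B = 1000 permutations (configurable; the
bundled experiments use 200–500 to keep runtimes in seconds).

With the published post-hoc couplings (controls −0.537, patients 0.089) and
group sizes (30/38), the interaction effect itself is modest: the slope
difference of 0.626 carries a t noncentrality of ~2.7 against a forming
threshold of |t| > 3.44, so a planted 3x3x3 block is recovered in roughly
half of simulation repeats, not reliably. Post-hoc correlations on selected
voxels are biased away from zero (circular selection), so printed post-hoc
values likely understate what a detectable peak effect must have been; the
recovery experiments here should be read with that in mind.

## Cross-validated reliability

For each of 1000 iterations, subjects are randomly partitioned into 3
near-equal folds (sizes differ by at most 1, e.g. 38 -> 13/13/12); per fold,
SSRT is regressed on activation in the other folds (univariate, no age —
the published description of this step mentions only the activation
regression) and the Pearson correlation of predicted vs observed SSRT on
the held-out fold is recorded; the 3 values are averaged. Prediction is
reliable when >= 95% of the 1000 averages exceed zero. A fold with constant
predictions or outcomes contributes 0 with a warning. Note the orientation:
a strong *negative* coupling yields *positive* predicted-observed
correlations.

Two properties of this statistic matter for interpretation. First, for a
fixed sample the CV distribution reflects that sample's own empirical
coupling, so the exchangeable null must be simulated with a fresh
independent sample per iteration (proportion positive then sits near 50%);
forcing a fixed sample's empirical r to exactly zero instead produces a
strongly *negative* CV distribution, because complementary train/test folds
of a zero-total-correlation sample are anti-correlated by construction.
Second, at weak couplings the fixed-sample CV distribution is bimodal and
often mostly negative — a patient-like sample with empirical r = 0.089
yields ~16% positive with grand mean r ~ −0.15 in the bundled experiment,
qualitatively matching the reported patient figures (24.9%, mean −0.14)
even though that outcome depends on the particular sample and is not a
calibration target here.

## Resting-state connectivity

The rest generator plants a 0.01–0.1 Hz band-limited latent signal in a
seed block; target voxels mix the latent with independent band-limited
noise at the requested correlation; background voxels carry band-limited
plus broadband noise. Confounds are motion random walks (per-volume step sd
0.02 mm/deg, keeping typical cumulative motion under the 1 mm / 1.0 degree
QC bounds of a compliant subject), CSF/WM series, and optional spike
volumes; they enter voxel signals through random loadings. Motion QC fails
a run only when motion strictly exceeds the bounds, per the printed "more
than" wording.

Denoising follows the published order: drop the first 4 volumes, linear
detrend, regress out 6 motion parameters + first differences + CSF + WM +
one indicator per flagged outlier volume (rank-deficient confound columns
dropped via pivoted QR with a warning), then a zero-phase 4th-order
Butterworth 0.01–0.1 Hz band-pass (the original toolbox's exact filter and
scrubbing thresholds are unpublished; scrubbing here flags framewise
displacement > 0.9 mm or global-signal |z| > 5). Seed FC is the Pearson
correlation of each voxel with the mean seed series, Fisher z-transformed
with |r| clipped to 1 − 1e-7; zero-variance voxels are masked. Group
comparison reuses the two-sample age-covaried model and permutation cluster
FDR. With planted couplings 0.6 vs 0.3 and 30/38 subjects the group
difference is recovered essentially always (the between-group z difference
of ~0.37 is an order of magnitude above its standard error at 206 usable
volumes).

## Problem sizes and determinism

The bundled experiments run on 10x10x10 (analysis scripts) or 8x8x8 (test
recovery experiments) voxel grids with 200–500 permutations and
1000 CV iterations — sizes chosen so each script completes in seconds while
keeping every statistical property visible; all are configurable upward.
A single master seed fans out to stages by hashing the stage name, so adding
a stage never perturbs earlier draws and every artifact is reproducible
byte-for-byte from config + seed.

## What the synthetic data do not show

The generators realise the assumptions of their own analysis models
(ex-Gaussian go RTs, context-independent race, linear confound mixing,
stationary band-limited signals, Gaussian noise). Passing tests therefore
demonstrate the correctness and calibration of the *pipeline*, not that
real BOLD or behaviour satisfies those assumptions: violations such as
context-dependent stopping, RT anticipations, non-linear motion artefacts,
physiological noise spectra, or spatial autocorrelation of real clusters
are out of scope, as are spatial preprocessing (realignment, normalisation)
and anatomical localisation — all maps live on an abstract aligned grid.
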