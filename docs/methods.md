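# Methods

This note documents the generative model behind the synthetic data, the
analysis procedures, their tunable parameters, and the numerical and design
choices made where more than one reasonable option existed. It states no
empirical result beyond what the test suite and `scripts/acceptance.py`
compute.

## Design generator

A session has `n_runs` = 8 runs of `trials_per_run` = 48 trials,
alternating attention and expectation blocks (first condition
configurable). Four cue shapes are fixed for the whole experiment: the
first two predict faces, the last two names. Each run shows one
face-predictive and one name-predictive shape; the four face/name pairings
rotate over a condition's runs in the cycle (F1,N1), (F2,N2), (F1,N2),
(F2,N1), so each face shape co-occurs equally often with each name shape
and — important for the crossnobis fold scheme below — each
condition × category × shape cell appears exactly once in the first half
and once in the second half of a condition's runs.

Counterbalancing is exact, not stochastic: per run, each cue appears on
half the trials, each target category on half the trials, and within each
cue's trials the target matches the prediction on exactly
`expectation_validity` of them (18 of 24 in expectation at defaults; 12 of
24 in attention, whose contingency is always 50%). `trials_per_run` must
be divisible by 8 so all cue × category × cueing cells balance; a
non-integer validity count raises with the offending cell named.

Cue–target (CTI) and inter-trial (ITI) intervals are drawn from the grid
{2500, 3200, …, 6000} ms. When `trials_per_run` is a multiple of 6 the
grid is tiled and permuted within each run, so the per-run mean is exactly
4250 ms and a default trial averages 0.5 + 4.25 + 0.5 + 4.25 = 9.5 s
(run: 7.6 min); otherwise jitters are drawn uniformly with replacement.
The balancing scheme within runs is this package's choice — only the
distribution and its mean are constrained by the paradigm.

## BOLD forward model

Volumes live on a common voxel grid (default 24³) containing four disjoint
cubic ROIs named for the regions the planted effects emulate (`itg-like`,
`occ-like`, `fg-like`, `fo-like`). Per participant, patterns are drawn
once from a standard normal over ROI voxels and scaled by amplitudes
expressed in per-voxel signal SD units, directly comparable to `noise_sd`
(default 1.0):

- `category_amplitude[condition][roi]` — cue-epoch face/name pattern
  (face = +p, name = −p). Defaults plant strong attention-category codes
  in `itg-like`, strong expectation codes in `occ-like`, strong codes for
  both conditions in `fg-like`, and weak/no codes in `fo-like`, mirroring
  the qualitative topography the analyses are meant to detect.
- `shared_pattern_weight` (default 0.8) — in `fg-like` only, the two
  conditions' category patterns mix a common component with
  condition-specific ones (convex mix renormalized to unit per-voxel
  variance), so cross-condition decoding succeeds only there.
- `condition_amplitude` (1.0) — a pattern added to cue betas with
  opposite sign in attention vs. expectation, supporting
  condition decoding.
- `shape_amplitude` (0.5) — one pattern per physical cue shape, shared
  across conditions; carries shape but not category information, which is
  what the cue-pair swap control removes.
- `reinstatement_weight` (default attention 0.0, expectation 0.8) —
  target-epoch category patterns mix the cue-epoch pattern with an
  independent perceptual pattern; this drives cue→target cross-decoding
  and positive ranking slopes only where it is non-zero. The asymmetric
  default encodes the planted ground truth that anticipatory tuning
  generalizes to perception in expectation but not attention.

A run's series is `Y = X_task · B_true + noise_sd · N(0,1)`, with
`X_task` the HRF-convolved cue/target regressors, so GLM estimation on the
same design recovers `B_true` exactly at zero noise. With every amplitude
zero the output is white noise — the basis of all calibration tests.
`quick_betamaps` skips the time-series round trip and returns
`B_true + beta_noise_sd · N(0,1)` with white residual series attached; it
is used for simulation studies (group calibration, recovery) where the
estimation path itself is not under test.

What the generator does *not* emulate: spatial autocorrelation and
physiological noise, scanner drift and motion, hemodynamic nonlinearity,
anatomical variability (all participants share one grid), and EEG volume
conduction. Passing tests therefore show that the *procedures* are
correct and calibrated under their stated assumptions, not that real data
would yield these effect sizes.

## GLM

The canonical HRF is the standard double-gamma (peak 6 s, undershoot 16 s,
unit dispersions, peak:undershoot ratio 6), sampled and normalized to unit
peak; an infinite ratio degenerates to a single non-negative gamma. Task
boxcars are built at a microtime resolution of TR/16 and sampled at volume
onsets after convolution. Cue regressors span the 500 ms cue plus that
trial's CTI (two per run: one per predicted category); target regressors
span the 500 ms target (four per run: category × cueing). Motion columns
are appended unconvolved; an intercept is always present. Estimation is
per-run OLS — no cross-run leakage, matching the leave-one-run-out logic
downstream. No prewhitening or high-pass filtering is applied by default
(the synthetic noise is white); rank-deficient designs fall back to the
pseudoinverse with a warning naming the collinear columns. Target cells a
run never shows yield all-zero columns that are kept and flagged.

## Searchlight decoding

Sphere membership uses the strict inequality ‖v‖ < r, the convention that
yields exactly 251 voxels at r = 4; offsets are enumerated
lexicographically and spheres are restricted to in-mask voxels (< 2 voxels
⇒ NaN). The classifier is a linear SVM with C = 1 and no feature scaling
beyond per-fold mean-centering with training-set means. Balanced accuracy
(mean of per-class recalls) makes chance 0.5 regardless of imbalance.
Pseudoruns pair each attention run with the temporally adjacent
expectation run. Fold hygiene is enforced structurally: train/test
disjoint, training folds class-balanced. Decision ties resolve
deterministically through the fixed class order.

## Group statistics

Second-level inference is a voxel-wise one-sample t-test against 0.5
(accuracies) or 0 (differences); paired contrasts are one-sample tests on
participant-wise difference maps. Cluster correction thresholds voxels at
uncorrected p < 0.001, labels 26-connected clusters, and refers their
sizes to a max-cluster-size null built from sign-flips of the de-meaned
participant maps; a cluster is significant when its permutation p value
(1 + #{null ≥ size})/(n_perm + 1) is ≤ α. This permutation analogue was
chosen over random-field theory because it controls the same familywise
rate and is directly testable by simulation. LOSO ROIs re-run the
corrected analysis on each leave-one-participant-out subsample; 26-
connectivity and the trimming cell definition (participant × condition)
are this package's choices where convention varies.

RT trimming discards trials strictly beyond mean ± 2 SD of their cell,
with statistics from the untrimmed cell in a single pass (re-trimming a
trimmed table may remove more — the rule is deliberately single-pass);
cells with < 3 trials pass through with a warning. Note that a single
extreme outlier can inflate the cell SD enough to survive the rule — with
RTs {500, 500, 500, 500, 5000}, the mean is 1400 and the sample SD
≈ 2012, so |5000 − 1400| = 3600 < 2·SD and nothing is discarded; the test
suite pins this behavior against a brute-force application of the rule.

## Voxel selectivity ranking

Cells are category × run (8 per condition). Per voxel, cue betas are
sorted ascending with a stable sort (ties break by cell index,
deterministically), the order is applied to that voxel's target betas
(cued/uncued collapsed per category), reordered vectors are averaged over
ROI voxels *before* the slope fit — matching the "average, then fit one
line" reading of the procedure — and the slope is OLS over ranks coded
1…8 with unit spacing. Group tests: right-tailed one-sample t per
ROI × condition, FDR over that family; paired two-tailed t between
conditions where at least one survived, FDR again; a control re-fits on
the first 7 ranks. Zero-variance slope sets are reported with a capped t
and a warning.

## Crossnobis RDMs and fusion

fMRI folds split each condition's runs into first and second halves; the
rotating cue pairings guarantee each of the 8 cells appears once per fold.
EEG folds split each cell's epochs half/half. The noise covariance is the
training fold's residual covariance shrunk toward its diagonal (weight
0.1 by default) and pseudoinverted; shrinkage stabilizes the inverse when
residual samples are scarce relative to features. LDC values are averaged
over the two fold assignments, making the estimator unbiased — negative
distances are expected under the null and are kept.

EEG RDM entries are smoothed over time with a centered five-point moving
average (truncated at the edges); smoothing is applied to RDM entries,
not to the commonality series. Group analysis averages RDMs across
participants *before* fusion. Fusion is the squared Pearson correlation
of the 28-element lower triangles. Commonality of model A is
C = sr²(EEG, fMRI·others) − sr²(EEG, fMRI·others+A), with each squared
semipartial realized by regressing the fMRI vector on the stated model
vectors (with intercept) and correlating the residual with EEG. The
2-model variant simply passes only the category and cue models. The
implementation is verified against an independent all-subsets-regression
oracle to 1e−10 on random instances.

The permutation test relabels the 8 cells of the EEG RDMs (one uniform
random permutation per iteration, applied consistently across time;
default 5000 iterations). Points above the per-time (1 − α) quantile of
permuted values form candidate windows; a window is significant when it
is strictly longer than the (1 − α) quantile of the permutations' maximal
supra-threshold run lengths. What exactly is permuted is ambiguous in
this family of methods (cell labels, time points, or matrix entries);
cell labels were chosen because they preserve the within-time covariance
structure while breaking the model alignment. A structural consequence:
the 2·4!·4!/8! ≈ 2.9% of permutations that preserve the category
partition reproduce a category commonality series exactly, so no category
window can reach a cluster p below ≈ 0.029, and only effects sustained
over a long window clear the null. The synthetic EEG ramp amplitude
default (2.0 sensor-noise SDs at target onset) was set with this property
in mind: it produces windows spanning roughly the second half of the
anticipatory interval, the regime the method can detect.

## Synthetic EEG and behavior

Epochs span −200…1550 ms around cue onset in 25 ms steps over 30 channels
(1550 ms is target onset in the EEG session, which used brief unjittered
stimuli). Channel patterns: a category pattern scaled by a linear ramp
from cue onset to target onset, a sustained condition pattern, and an
early Gaussian transient (150 ± 50 ms) per physical cue shape; white
sensor noise per sample. Behavior draws log-normal RTs (median 650 ms,
log-SD 0.25) with a cueing benefit of 25 ms applied symmetrically
(cued −12.5, uncued +12.5) in expectation only, and Bernoulli accuracy
0.93.

## Problem sizes and determinism

Simulation-based tests run at reduced scale chosen as the smallest sizes
at which the tested property is identifiable: 24-trial runs (divisible by
both 8 and 6, preserving every counterbalancing invariant), grids of
~8–12 voxels per side with 27-voxel ROIs, searchlight radius 2,
10–12 simulated participants, 500–1500 permutations. All randomness flows
through `numpy.random.default_rng` seeds carried in specs or arguments;
the pipeline is byte-reproducible for a fixed config, which the test
suite asserts end to end.

## Known limitations

Planted patterns are spatially white within ROIs, so searchlight accuracy
jumps abruptly at ROI borders rather than varying smoothly; the
permutation cluster-extent null is exact for exchangeable participants
but the voxel-level p < 0.001 height threshold is parametric; EEG
channels are exchangeable (no montage geometry); and the behavioral
module provides only summary conveniences, not the full repeated-measures
ANOVA machinery of a behavioral analysis package.
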