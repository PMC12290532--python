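"""Forward BOLD model with planted multivariate effects.

The generator plants, per participant, spatial activity patterns over four
disjoint region-of-interest (ROI) blocks of a common voxel grid, loosely
named after regions where anticipatory category information tends to appear:
``itg-like`` (inferior temporal), ``occ-like`` (occipital), ``fg-like``
(fusiform) and ``fo-like`` (frontal operculum). Patterns are standard-normal
voxel weights scaled by interpretable amplitudes:

* a *category* pattern per condition and ROI (face = +pattern, name =
  -pattern on cue-epoch betas); in the ``fg-like`` ROI the attention and
  expectation category patterns share a common component controlled by
  ``shared_pattern_weight``, so cross-condition decoding succeeds only there;
* a *condition* pattern (sign-flipped between attention and expectation cue
  epochs) supporting attention-vs-expectation decoding;
* a *cue-shape* transient pattern per physical shape, shared across
  conditions, which carries shape (but not category) information;
* target-epoch category patterns that reinstate the cue-epoch pattern with a
  per-condition ``reinstatement_weight`` (the remainder is an independent
  perceptual pattern), driving cue-to-target cross-decoding and the voxel
  selectivity ranking.

Voxel time series are the HRF-convolved event regressors times these
ground-truth betas plus white Gaussian noise; with all amplitudes zero the
output is pure noise. The true betas are returned so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONDITIONS, DesignSpec
from .glm import (CUE_LABELS, TARGET_LABELS, TASK_LABELS, BetaMaps,
                  DesignMatrix, HRFSpec, RunFit, build_design_matrix)

ROI_NAMES = ("itg-like", "occ-like", "fg-like", "fo-like")


def default_roi_masks(grid_shape: tuple[int, int, int],
                      roi_extent: int | None = None) -> dict[str, np.ndarray]:
    """Four disjoint cubic ROI masks in the corners of the grid."""
    nx, ny, nz = grid_shape
    e = roi_extent if roi_extent is not None else max(2, min(grid_shape) // 4)
    if 2 * e > min(nx, ny):
        raise ValueError("grid too small for two ROI cubes per axis")
    corners = {
        "itg-like": (0, 0),
        "occ-like": (nx - e, 0),
        "fg-like": (0, ny - e),
        "fo-like": (nx - e, ny - e),
    }
    masks = {}
    z0 = (nz - e) // 2
    for name, (x0, y0) in corners.items():
        m = np.zeros(grid_shape, dtype=bool)
        m[x0:x0 + e, y0:y0 + e, z0:z0 + e] = True
        masks[name] = m
    return masks


def _default_category_amplitude() -> dict[str, dict[str, float]]:
    return {
        "attention": {"itg-like": 1.0, "occ-like": 0.4, "fg-like": 1.0, "fo-like": 0.0},
        "expectation": {"itg-like": 0.4, "occ-like": 1.0, "fg-like": 1.0, "fo-like": 0.4},
    }


def _default_reinstatement() -> dict[str, float]:
    return {"attention": 0.0, "expectation": 0.8}


@dataclass
class PlantedEffectSpec:
    """Ground-truth effect structure planted in the synthetic BOLD data.

    Amplitudes are per-voxel signal standard deviations (patterns are unit
    per-voxel variance), directly comparable to ``noise_sd``. Weights lie in
    [0, 1]; ``shared_pattern_weight`` only acts in the ``fg-like`` ROI and
    ``reinstatement_weight`` may differ by condition.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    roi_masks: dict[str, np.ndarray] | None = None
    category_amplitude: dict[str, dict[str, float]] = field(
        default_factory=_default_category_amplitude)
    shared_pattern_weight: float = 0.8
    reinstatement_weight: dict[str, float] | float = field(
        default_factory=_default_reinstatement)
    condition_amplitude: float = 1.0
    shape_amplitude: float = 0.5
    target_amplitude: float = 1.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.roi_masks is None:
            self.roi_masks = default_roi_masks(self.grid_shape)
        flat = [np.asarray(m, dtype=bool).ravel() for m in self.roi_masks.values()]
        if np.any(np.sum(flat, axis=0) > 1):
            raise ValueError("ROI masks must be disjoint")
        if not 0.0 <= self.shared_pattern_weight <= 1.0:
            raise ValueError("shared_pattern_weight must lie in [0, 1]")
        for w in self._reinstatement_map().values():
            if not 0.0 <= w <= 1.0:
                raise ValueError("reinstatement_weight must lie in [0, 1]")

    def _reinstatement_map(self) -> dict[str, float]:
        w = self.reinstatement_weight
        if isinstance(w, dict):
            return {c: float(w.get(c, 0.0)) for c in CONDITIONS}
        return {c: float(w) for c in CONDITIONS}

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


def _mix(primary: np.ndarray, secondary: np.ndarray, w: float) -> np.ndarray:
    """Convex pattern mix re-normalized to unit per-voxel variance."""
    if w in (0.0, 1.0):
        return primary if w == 1.0 else secondary
    scale = float(np.sqrt(w ** 2 + (1.0 - w) ** 2))
    return (w * primary + (1.0 - w) * secondary) / scale


@dataclass
class ParticipantPatterns:
    """Per-participant ground-truth voxel patterns (flat grid vectors)."""

    cue_category: dict[str, np.ndarray]      # condition -> pattern
    target_category: dict[str, np.ndarray]   # condition -> pattern
    condition: np.ndarray
    shape: dict[str, np.ndarray]             # physical shape -> pattern

    def cue_beta(self, effects: PlantedEffectSpec, condition: str,
                 category: str, shape: str) -> np.ndarray:
        sign = 1.0 if category == "face" else -1.0
        cond_sign = 1.0 if condition == "attention" else -1.0
        return (sign * self.cue_category[condition]
                + cond_sign * effects.condition_amplitude * self.condition
                + effects.shape_amplitude * self.shape[shape])

    def target_beta(self, effects: PlantedEffectSpec, condition: str,
                    category: str) -> np.ndarray:
        sign = 1.0 if category == "face" else -1.0
        return sign * effects.target_amplitude * self.target_category[condition]


def draw_patterns(effects: PlantedEffectSpec, rng: np.random.Generator,
                  cue_shapes: tuple[str, ...] = DesignSpec().cue_shapes
                  ) -> ParticipantPatterns:
    """Draw one participant's planted patterns (standard normal over ROI voxels)."""
    n_vox = effects.n_voxels
    reinst = effects._reinstatement_map()

    cue_category = {c: np.zeros(n_vox) for c in CONDITIONS}
    target_category = {c: np.zeros(n_vox) for c in CONDITIONS}
    condition_pattern = np.zeros(n_vox)
    shape_patterns = {s: np.zeros(n_vox) for s in cue_shapes}

    for roi, mask in effects.roi_masks.items():
        idx = np.flatnonzero(np.asarray(mask).ravel())
        k = idx.size
        shared = rng.standard_normal(k)
        per_cond_q = {}
        for cond in CONDITIONS:
            specific = rng.standard_normal(k)
            w = effects.shared_pattern_weight if roi == "fg-like" else 0.0
            q = _mix(shared, specific, w)
            per_cond_q[cond] = q
            amp = effects.category_amplitude.get(cond, {}).get(roi, 0.0)
            cue_category[cond][idx] = amp * q
            perceptual = rng.standard_normal(k)
            target_category[cond][idx] = _mix(q, perceptual, reinst[cond])
        condition_pattern[idx] = rng.standard_normal(k)
        for s in cue_shapes:
            shape_patterns[s][idx] = rng.standard_normal(k)

    return ParticipantPatterns(cue_category=cue_category,
                               target_category=target_category,
                               condition=condition_pattern,
                               shape=shape_patterns)


def true_run_betas(run_trials: pd.DataFrame, effects: PlantedEffectSpec,
                   patterns: ParticipantPatterns) -> np.ndarray:
    """Ground-truth (n_task_regressors x n_voxels) betas for one run."""
    condition = run_trials.condition.iloc[0]
    shape_of = {}
    for row in run_trials.itertuples():
        shape_of[row.predicted_category] = row.cue_shape
    B = np.zeros((len(TASK_LABELS), effects.n_voxels))
    for i, label in enumerate(TASK_LABELS):
        parts = label.split("_")
        if parts[0] == "cue":
            category = parts[1]
            B[i] = patterns.cue_beta(effects, condition, category,
                                     shape_of[category])
        else:
            category = parts[1]
            B[i] = patterns.target_beta(effects, condition, category)
    return B


@dataclass
class BoldSession:
    """One participant's synthetic session: volumes, designs and ground truth."""

    volumes_by_run: dict[int, np.ndarray]
    designs: dict[int, DesignMatrix]
    true_betas_by_run: dict[int, np.ndarray]
    patterns: ParticipantPatterns
    effects: PlantedEffectSpec

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.effects.grid_shape


def _n_volumes_for(run_trials: pd.DataFrame, tr_ms: float,
                   tail_ms: float = 30000.0) -> int:
    last = run_trials.iloc[-1]
    end_ms = float(last.target_onset_ms + 500.0 + last.iti_ms) + tail_ms
    return int(np.ceil(end_ms / tr_ms))


def generate_bold(trials: pd.DataFrame, effects: PlantedEffectSpec,
                  seed: int, tr_ms: float = 1730.0,
                  hrf: HRFSpec = HRFSpec(),
                  n_volumes: int | None = None) -> BoldSession:
    """Simulate one participant's BOLD runs from a trial table.

    Each run's series is ``X_task @ B_true + noise_sd * N(0, 1)`` where
    ``X_task`` holds the HRF-convolved cue/target regressors and ``B_true``
    the planted patterns. Runs longer than the provided ``n_volumes`` raise.
    """
    rng = np.random.default_rng(seed)
    patterns = draw_patterns(effects, rng)
    volumes_by_run, designs, truths = {}, {}, {}
    for run_index in sorted(trials.run_index.unique()):
        run_trials = trials[trials.run_index == run_index]
        nv = n_volumes if n_volumes is not None else _n_volumes_for(run_trials, tr_ms)
        design = build_design_matrix(run_trials, tr_ms=tr_ms, n_volumes=nv, hrf=hrf)
        B = true_run_betas(run_trials, effects, patterns)
        X_task = design.matrix[:, :len(TASK_LABELS)]
        Y = X_task @ B
        if effects.noise_sd > 0:
            Y = Y + effects.noise_sd * rng.standard_normal(Y.shape)
        volumes_by_run[int(run_index)] = Y
        designs[int(run_index)] = design
        truths[int(run_index)] = B
    return BoldSession(volumes_by_run=volumes_by_run, designs=designs,
                       true_betas_by_run=truths, patterns=patterns,
                       effects=effects)


def quick_betamaps(trials: pd.DataFrame, effects: PlantedEffectSpec,
                   seed: int, beta_noise_sd: float = 1.0,
                   n_residual_samples: int = 60) -> BetaMaps:
    """Planted betas plus white noise, skipping the time-series round trip.

    A fast surrogate for ``generate_bold`` + GLM used in simulation studies:
    betas equal the ground truth plus ``beta_noise_sd`` Gaussian noise, and
    white-noise residual series are attached so covariance-based distances
    remain computable. The estimation path itself is exercised elsewhere.
    """
    rng = np.random.default_rng(seed)
    patterns = draw_patterns(effects, rng)
    maps = BetaMaps(effects.grid_shape)
    for run_index in sorted(trials.run_index.unique()):
        run_trials = trials[trials.run_index == run_index]
        B = true_run_betas(run_trials, effects, patterns)
        B = B + beta_noise_sd * rng.standard_normal(B.shape)
        residuals = rng.standard_normal((n_residual_samples, effects.n_voxels))
        maps.add_run(RunFit(betas=B, residuals=residuals,
                            labels=list(TASK_LABELS),
                            run_index=int(run_index),
                            condition=str(run_trials.condition.iloc[0])))
    return maps
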