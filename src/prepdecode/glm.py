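"""Run-wise GLM: canonical HRF, design matrices, and OLS beta estimation.

Each run is modeled with two cue regressors (one per predicted category; a
run only ever shows one condition) and four target regressors (category x
cueing). Cue events span the 500 ms cue plus that trial's CTI, so the
regressor covers the whole anticipatory interval; target events span the
500 ms target presentation. Boxcars are built at a microtime resolution of
TR/16, convolved with a canonical double-gamma HRF, and sampled at volume
acquisition times. Motion nuisance columns (unconvolved) and an intercept
complete the matrix. Betas are estimated by ordinary least squares per run,
and residuals are kept for the cross-validated Mahalanobis distances
downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

CUE_LABELS = ("cue_face", "cue_name")
TARGET_LABELS = (
    "target_face_cued", "target_face_uncued",
    "target_name_cued", "target_name_uncued",
)
TASK_LABELS = CUE_LABELS + TARGET_LABELS

MICROTIME_OVERSAMPLING = 16


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma canonical HRF parameters (seconds).

    Defaults follow the standard canonical shape: response peak at 6 s,
    undershoot at 16 s, unit dispersions, peak:undershoot ratio 6. An
    infinite ratio degenerates to a single (everywhere non-negative) gamma.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    peak_undershoot_ratio: float = 6.0
    duration_s: float = 32.0

    def __post_init__(self) -> None:
        for name in ("peak_delay_s", "undershoot_delay_s", "peak_dispersion_s",
                     "undershoot_dispersion_s", "peak_undershoot_ratio", "duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def canonical_hrf(spec: HRFSpec = HRFSpec(), dt_s: float = 0.1) -> np.ndarray:
    """Sample the canonical double-gamma HRF on a grid of step ``dt_s``.

    The kernel is the difference of two gamma densities (shape = delay /
    dispersion, scale = dispersion), normalized to unit peak. Its argmax sits
    near ``peak_delay_s`` and the undershoot is negative unless the
    peak:undershoot ratio is infinite.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be strictly positive")
    t = np.arange(0.0, spec.duration_s + dt_s / 2, dt_s)
    peak = gamma_dist.pdf(t, spec.peak_delay_s / spec.peak_dispersion_s,
                          scale=spec.peak_dispersion_s)
    kernel = peak.copy()
    if np.isfinite(spec.peak_undershoot_ratio):
        under = gamma_dist.pdf(t, spec.undershoot_delay_s / spec.undershoot_dispersion_s,
                               scale=spec.undershoot_dispersion_s)
        kernel = kernel - under / spec.peak_undershoot_ratio
    peak_height = np.max(np.abs(kernel))
    if peak_height > 0:
        kernel = kernel / peak_height
    return kernel


@dataclass
class DesignMatrix:
    """One run's design: (n_volumes x n_regressors) matrix with labeled columns."""

    matrix: np.ndarray
    labels: list[str]
    run_index: int
    tr_ms: float
    condition: str
    empty_columns: list[str] = field(default_factory=list)

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.labels)


def _event_spans(run_trials: pd.DataFrame, cue_ms: float, target_ms: float
                 ) -> dict[str, list[tuple[float, float]]]:
    """Map task regressor label -> list of (onset_ms, duration_ms)."""
    spans: dict[str, list[tuple[float, float]]] = {lab: [] for lab in TASK_LABELS}
    for row in run_trials.itertuples():
        if row.predicted_category not in ("face", "name"):
            raise ValueError(f"unknown predicted_category {row.predicted_category!r}")
        if row.cueing not in ("cued", "uncued"):
            raise ValueError(f"unknown cueing label {row.cueing!r}")
        spans[f"cue_{row.predicted_category}"].append(
            (row.cue_onset_ms, cue_ms + row.cti_ms))
        spans[f"target_{row.target_category}_{row.cueing}"].append(
            (row.target_onset_ms, target_ms))
    return spans


def build_design_matrix(
    run_trials: pd.DataFrame,
    tr_ms: float,
    n_volumes: int,
    hrf: HRFSpec = HRFSpec(),
    motion: np.ndarray | None = None,
    cue_ms: float = 500.0,
    target_ms: float = 500.0,
) -> DesignMatrix:
    """Build the HRF-convolved design matrix for one run.

    ``run_trials`` must contain a single run of a single condition. Task
    boxcars are built at TR/16 microtime resolution, convolved, and sampled
    at volume onsets. ``motion`` (n_volumes x 6, optional) is appended
    unconvolved; an intercept column is always last. Target cells that never
    occur in the run yield all-zero columns, which are kept but recorded in
    ``empty_columns``.
    """
    runs = run_trials.run_index.unique()
    if len(runs) != 1:
        raise ValueError("build_design_matrix expects exactly one run")
    conditions = run_trials.condition.unique()
    if len(conditions) != 1:
        raise ValueError("a run must contain a single condition")

    run_end_ms = n_volumes * tr_ms
    last_event_end = float((run_trials.target_onset_ms + target_ms).max())
    if last_event_end > run_end_ms:
        raise ValueError(
            f"events end at {last_event_end:.0f} ms but the run has only "
            f"{n_volumes} volumes ({run_end_ms:.0f} ms)")

    dt_s = tr_ms / 1000.0 / MICROTIME_OVERSAMPLING
    n_fine = n_volumes * MICROTIME_OVERSAMPLING
    kernel = canonical_hrf(hrf, dt_s=dt_s)
    spans = _event_spans(run_trials, cue_ms, target_ms)

    columns, labels, empty = [], [], []
    for label in TASK_LABELS:
        boxcar = np.zeros(n_fine)
        for onset_ms, dur_ms in spans[label]:
            i0 = int(round(onset_ms / 1000.0 / dt_s))
            i1 = int(round((onset_ms + dur_ms) / 1000.0 / dt_s))
            boxcar[i0:min(i1, n_fine)] = 1.0
        if not np.any(boxcar):
            empty.append(label)
        convolved = np.convolve(boxcar, kernel)[:n_fine]
        columns.append(convolved[::MICROTIME_OVERSAMPLING])
        labels.append(label)

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_volumes:
            raise ValueError("motion regressors must have one row per volume")
        for j in range(motion.shape[1]):
            columns.append(motion[:, j])
            labels.append(f"motion_{j}")

    columns.append(np.ones(n_volumes))
    labels.append("intercept")
    return DesignMatrix(
        matrix=np.column_stack(columns), labels=labels,
        run_index=int(runs[0]), tr_ms=tr_ms, condition=str(conditions[0]),
        empty_columns=empty,
    )


@dataclass
class RunFit:
    """OLS fit of one run: betas (n_regressors x n_voxels) and residuals."""

    betas: np.ndarray
    residuals: np.ndarray
    labels: list[str]
    run_index: int
    condition: str

    def beta(self, label: str) -> np.ndarray:
        return self.betas[self.labels.index(label)]


def fit_glm(volumes: np.ndarray, design: DesignMatrix) -> RunFit:
    """Voxel-wise OLS for one run.

    ``volumes`` is (n_volumes x n_voxels). Rank-deficient designs fall back
    to the pseudoinverse with a warning naming the collinear columns.
    Residuals are returned for covariance estimation in the LDC distances.
    """
    Y = np.asarray(volumes, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != design.n_volumes:
        raise ValueError(
            f"volumes must be (n_volumes={design.n_volumes}, n_voxels)")
    X = design.matrix
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [design.labels[i] for i in np.nonzero(diag < 1e-8 * diag.max())[0]]
        warnings.warn(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad}; using pseudoinverse", RuntimeWarning)
        betas = np.linalg.pinv(X) @ Y
    else:
        betas, *_ = np.linalg.lstsq(X, Y, rcond=None)
    residuals = Y - X @ betas
    return RunFit(betas=betas, residuals=residuals, labels=list(design.labels),
                  run_index=design.run_index, condition=design.condition)


class BetaMaps:
    """Per-run beta estimates over a common voxel grid.

    Maps (run, regressor label) to a flat voxel vector; ``grid_shape``
    records the 3-D layout for export. Residual series are retained per run.
    """

    def __init__(self, grid_shape: tuple[int, int, int]):
        self.grid_shape = tuple(grid_shape)
        self.runs: dict[int, RunFit] = {}

    def add_run(self, fit: RunFit) -> None:
        self.runs[fit.run_index] = fit

    def beta(self, run_index: int, label: str) -> np.ndarray:
        return self.runs[run_index].beta(label)

    def beta_volume(self, run_index: int, label: str) -> np.ndarray:
        return self.beta(run_index, label).reshape(self.grid_shape)

    def residuals(self, run_index: int) -> np.ndarray:
        return self.runs[run_index].residuals

    @property
    def run_indices(self) -> list[int]:
        return sorted(self.runs)

    def runs_of_condition(self, condition: str) -> list[int]:
        return [r for r in self.run_indices if self.runs[r].condition == condition]


def fit_session(volumes_by_run: dict[int, np.ndarray],
                designs: dict[int, DesignMatrix],
                grid_shape: tuple[int, int, int]) -> BetaMaps:
    """Fit every run of a session independently (no cross-run leakage)."""
    maps = BetaMaps(grid_shape)
    for run_index, design in designs.items():
        maps.add_run(fit_glm(volumes_by_run[run_index], design))
    return maps
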