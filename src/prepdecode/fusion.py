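"""Crossnobis RDMs, model-based EEG-fMRI fusion and commonality analysis.

Dissimilarities between the 8 condition x category x cue-shape cells are
cross-validated Mahalanobis distances (linear discriminant contrast, LDC):
with cell mean patterns split into two independent folds,

    d(a, b) = mean over the two fold assignments of
              (mu_a,train - mu_b,train) Sigma_train^+ (mu_a,test - mu_b,test)^T

where Sigma_train is the (shrinkage-regularized) covariance of the training
fold's residuals over features and ^+ the pseudoinverse. Because training
and test differences are independent, the estimator is unbiased: its null
expectation is zero and negative values are legal.

Fusion correlates the group-average EEG RDM at each time point with a group
average fMRI ROI RDM (squared Pearson correlation of the 28-element lower
triangles). Commonality analysis attributes shared EEG-fMRI variance to a
model RDM (condition, category, or cue) as a difference of squared
semipartial correlations: the EEG-fMRI correlation after partialling the
*other* models out of the fMRI vector, minus the same after additionally
partialling the model of interest. Significance of a commonality time
course uses a cluster-based permutation test that relabels the 8 cells of
the EEG RDMs (consistently across time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eeg import CELL_ORDER, SyntheticEEG
from .glm import BetaMaps

N_CELLS = 8
_TRIL = np.tril_indices(N_CELLS, k=-1)

MODEL_NAMES = ("condition", "category", "cue")


def lower_triangle(rdm: np.ndarray) -> np.ndarray:
    """The 28 below-diagonal entries of an 8x8 RDM (row-major order)."""
    rdm = np.asarray(rdm)
    return rdm[..., _TRIL[0], _TRIL[1]]


def shrunk_covariance(residuals: np.ndarray, shrinkage: float = 0.1) -> np.ndarray:
    """Sample feature covariance shrunk toward its diagonal."""
    res = np.asarray(residuals, dtype=float)
    res = res - res.mean(axis=0)
    cov = res.T @ res / max(res.shape[0] - 1, 1)
    return (1.0 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))


def ldc_distance(patterns_a: np.ndarray, patterns_b: np.ndarray,
                 residuals_by_fold: tuple[np.ndarray, np.ndarray],
                 shrinkage: float = 0.1) -> float:
    """Cross-validated Mahalanobis distance between two cells.

    ``patterns_a``/``patterns_b`` are (2 folds x n_features) mean patterns;
    ``residuals_by_fold`` supplies the training-fold residual samples for
    the noise covariance. The two fold assignments are averaged.
    """
    a = np.atleast_2d(np.asarray(patterns_a, dtype=float))
    b = np.atleast_2d(np.asarray(patterns_b, dtype=float))
    if a.shape != b.shape or a.shape[0] != 2:
        raise ValueError("need mean patterns for both cells in both folds")
    vals = []
    for train in (0, 1):
        test = 1 - train
        sigma = shrunk_covariance(residuals_by_fold[train], shrinkage)
        delta_train = a[train] - b[train]
        delta_test = a[test] - b[test]
        vals.append(float(delta_train @ np.linalg.pinv(sigma) @ delta_test))
    return float(np.mean(vals))


def build_rdm(cell_patterns: np.ndarray,
              residuals_by_fold: tuple[np.ndarray, np.ndarray],
              shrinkage: float = 0.1) -> np.ndarray:
    """8x8 symmetric LDC RDM from (8 cells x 2 folds x n_features) patterns."""
    cp = np.asarray(cell_patterns, dtype=float)
    if cp.shape[:2] != (N_CELLS, 2):
        raise ValueError("cell_patterns must be (8 cells x 2 folds x features)")
    sig_inv = [np.linalg.pinv(shrunk_covariance(residuals_by_fold[f], shrinkage))
               for f in (0, 1)]
    rdm = np.zeros((N_CELLS, N_CELLS))
    for i in range(N_CELLS):
        for j in range(i):
            vals = []
            for train in (0, 1):
                test = 1 - train
                dt = cp[i, train] - cp[j, train]
                de = cp[i, test] - cp[j, test]
                vals.append(dt @ sig_inv[train] @ de)
            rdm[i, j] = rdm[j, i] = float(np.mean(vals))
    return rdm


# ---------------------------------------------------------------------------
# modality-specific RDM builders


def _shape_pools(trials: pd.DataFrame) -> dict[str, list[str]]:
    """Physical shapes per category in order of first appearance."""
    pools: dict[str, list[str]] = {"face": [], "name": []}
    for row in trials.sort_values(["run_index", "cue_onset_ms"]).itertuples():
        pool = pools[row.predicted_category]
        if row.cue_shape not in pool:
            pool.append(row.cue_shape)
    return pools


def fmri_cell_patterns(maps: BetaMaps, trials: pd.DataFrame,
                       roi_mask: np.ndarray
                       ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Cue-epoch cell patterns and fold residuals for one ROI.

    Folds split each condition's four runs into its first two and last two;
    with the rotating shape pairings every condition x category x shape cell
    is observed exactly once per fold. Residual series come from the
    training fold's runs, restricted to the ROI.
    """
    idx = np.flatnonzero(np.asarray(roi_mask).ravel())
    pools = _shape_pools(trials)
    patterns = np.zeros((N_CELLS, 2, idx.size))
    filled = np.zeros((N_CELLS, 2), dtype=bool)
    fold_runs: dict[int, list[int]] = {0: [], 1: []}
    for condition in ("attention", "expectation"):
        runs = maps.runs_of_condition(condition)
        for pos, run in enumerate(runs):
            fold = 0 if pos < len(runs) // 2 else 1
            fold_runs[fold].append(run)
            run_trials = trials[trials.run_index == run]
            shape_of = dict(zip(run_trials.predicted_category,
                                run_trials.cue_shape))
            for category in ("face", "name"):
                shape_index = pools[category].index(shape_of[category]) + 1
                cell = CELL_ORDER.index((condition, category, shape_index))
                patterns[cell, fold] = maps.beta(run, f"cue_{category}")[idx]
                filled[cell, fold] = True
    if not filled.all():
        missing = [CELL_ORDER[i] for i, f in enumerate(filled) if not f.all()]
        raise ValueError(f"cells not observed in both folds: {missing}")
    residuals = tuple(
        np.vstack([maps.residuals(r)[:, idx] for r in fold_runs[f]])
        for f in (0, 1))
    return patterns, residuals


def fmri_rdm(maps: BetaMaps, trials: pd.DataFrame, roi_mask: np.ndarray,
             shrinkage: float = 0.1) -> np.ndarray:
    patterns, residuals = fmri_cell_patterns(maps, trials, roi_mask)
    return build_rdm(patterns, residuals, shrinkage)


def eeg_rdm_series(eeg: SyntheticEEG, shrinkage: float = 0.1,
                   smooth_window: int = 5) -> np.ndarray:
    """Time-resolved (n_times x 8 x 8) LDC RDMs over channels.

    Epochs of each cell are split half/half into two folds; residuals are
    the training epochs' deviations from their cell means. After
    construction, each RDM entry is smoothed over time with a centered
    moving average (5 points by default).
    """
    cells = eeg.cell_index()
    n_times = eeg.times_ms.size
    fold_of = np.zeros(len(cells), dtype=int)
    for c in range(N_CELLS):
        rows = np.flatnonzero(cells == c)
        if rows.size < 2:
            raise ValueError(f"cell {CELL_ORDER[c]} needs at least 2 epochs")
        fold_of[rows[rows.size // 2:]] = 1

    rdms = np.zeros((n_times, N_CELLS, N_CELLS))
    for t in range(n_times):
        X = eeg.data[:, :, t]
        patterns = np.zeros((N_CELLS, 2, X.shape[1]))
        residuals = []
        for f in (0, 1):
            res_rows = []
            for c in range(N_CELLS):
                rows = np.flatnonzero((cells == c) & (fold_of == f))
                mu = X[rows].mean(axis=0)
                patterns[c, f] = mu
                res_rows.append(X[rows] - mu)
            residuals.append(np.vstack(res_rows))
        rdms[t] = build_rdm(patterns, tuple(residuals), shrinkage)
    if smooth_window and smooth_window > 1:
        rdms = smooth_moving_average(rdms, window=smooth_window, axis=0)
    return rdms


def average_rdms(rdms: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Group-average RDMs across participants (first axis)."""
    return np.mean(np.asarray(rdms, dtype=float), axis=0)


# ---------------------------------------------------------------------------
# model RDMs


def model_rdms() -> dict[str, np.ndarray]:
    """The three binary 8x8 model RDMs in the canonical cell order.

    ``condition``: 1 iff block condition differs. ``category``: 1 iff the
    predicted category differs, regardless of block or cue. ``cue``: 1 iff
    the physical cue shape differs — the same shapes serve both conditions,
    so cells differing only in condition share a shape and get 0.
    """
    models = {name: np.zeros((N_CELLS, N_CELLS)) for name in MODEL_NAMES}
    for i, (cond_i, cat_i, shape_i) in enumerate(CELL_ORDER):
        for j, (cond_j, cat_j, shape_j) in enumerate(CELL_ORDER):
            if i == j:
                continue
            models["condition"][i, j] = float(cond_i != cond_j)
            models["category"][i, j] = float(cat_i != cat_j)
            models["cue"][i, j] = float((cat_i, shape_i) != (cat_j, shape_j))
    return models


# ---------------------------------------------------------------------------
# fusion and commonality


def fusion_r2(eeg_vec: np.ndarray, fmri_vec: np.ndarray) -> float:
    """Squared Pearson correlation of two vectorized RDM lower triangles."""
    x = np.asarray(eeg_vec, dtype=float)
    y = np.asarray(fmri_vec, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must share length")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance RDM vector: fusion undefined", RuntimeWarning)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def _residualize(y: np.ndarray, predictors: np.ndarray | None) -> np.ndarray:
    """Residual of ``y`` after OLS on ``predictors`` plus an intercept."""
    n = y.size
    X = np.ones((n, 1))
    if predictors is not None and predictors.size:
        X = np.hstack([X, np.atleast_2d(predictors.T).T.reshape(n, -1)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _corr2(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def commonality(eeg_vec: np.ndarray, fmri_vec: np.ndarray,
                models: dict[str, np.ndarray],
                model_of_interest: str) -> float:
    """Commonality coefficient of one model for an EEG-fMRI pair.

    ``models`` holds the vectorized model RDMs entering the analysis (three
    for the full variant, two for the reduced category+cue variant). The
    coefficient is the squared semipartial correlation of EEG with fMRI
    partialling the *other* models out of fMRI, minus the same with the
    model of interest also partialled out. It may be negative and may
    exceed the fusion R^2; only its magnitude is usually plotted.
    """
    if model_of_interest not in models:
        raise KeyError(f"{model_of_interest!r} not among models {list(models)}")
    y = np.asarray(fmri_vec, dtype=float)
    e = np.asarray(eeg_vec, dtype=float)
    all_mat = np.column_stack([np.asarray(models[m], float) for m in models])
    if np.linalg.matrix_rank(np.column_stack([np.ones(y.size), all_mat])
                             ) < all_mat.shape[1] + 1:
        raise ValueError("model vectors are collinear")
    others = np.column_stack([np.asarray(v, float)
                              for m, v in models.items()
                              if m != model_of_interest]) \
        if len(models) > 1 else None
    r2_without = _corr2(e, _residualize(y, others))
    r2_with = _corr2(e, _residualize(y, all_mat))
    return r2_without - r2_with


def smooth_moving_average(series: np.ndarray, window: int = 5,
                          axis: int = 0) -> np.ndarray:
    """Centered moving average; edges use the available truncated window."""
    if window % 2 != 1:
        raise ValueError("window must be odd")
    x = np.moveaxis(np.asarray(series, dtype=float), axis, 0)
    half = window // 2
    out = np.empty_like(x)
    n = x.shape[0]
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = x[lo:hi].mean(axis=0)
    return np.moveaxis(out, 0, axis)


def fusion_series(eeg_rdms: np.ndarray, fmri_rdm_mat: np.ndarray,
                  models: dict[str, np.ndarray] | None = None,
                  times_ms: np.ndarray | None = None) -> pd.DataFrame:
    """Time course of fusion R^2 and per-model commonality for one ROI.

    ``models`` maps names to 8x8 model RDMs (defaults to all three).
    Commonality for each model uses all supplied models, so passing only
    the category and cue models yields the reduced two-model variant.
    """
    if models is None:
        models = model_rdms()
    model_vecs = {m: lower_triangle(v) for m, v in models.items()}
    fmri_vec = lower_triangle(fmri_rdm_mat)
    eeg_vecs = lower_triangle(eeg_rdms)
    rows = []
    for t in range(eeg_vecs.shape[0]):
        row = {"time_ms": float(times_ms[t]) if times_ms is not None else float(t),
               "r2": fusion_r2(eeg_vecs[t], fmri_vec)}
        for m in models:
            row[f"C_{m}"] = commonality(eeg_vecs[t], fmri_vec, model_vecs, m)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cluster-based permutation inference


def _commonality_residual_pair(fmri_vec: np.ndarray,
                               model_vecs: dict[str, np.ndarray],
                               interest: str) -> tuple[np.ndarray, np.ndarray]:
    """The two fixed fMRI residual vectors whose squared correlations with
    the EEG vector difference into the commonality coefficient."""
    others = np.column_stack([v for m, v in model_vecs.items() if m != interest]) \
        if len(model_vecs) > 1 else None
    all_mat = np.column_stack(list(model_vecs.values()))
    return (_residualize(fmri_vec, others), _residualize(fmri_vec, all_mat))


def _corr2_series(E: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of each row of ``E`` with ``v``."""
    Ec = E - E.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((Ec ** 2).sum(axis=1) * (vc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Ec @ vc) / denom
    r = np.nan_to_num(r)
    return r ** 2


def commonality_series(eeg_rdms: np.ndarray, fmri_rdm_mat: np.ndarray,
                       models: dict[str, np.ndarray], interest: str
                       ) -> np.ndarray:
    """Commonality of one model at every time point (vectorized)."""
    model_vecs = {m: lower_triangle(v) for m, v in models.items()}
    e1, e2 = _commonality_residual_pair(lower_triangle(fmri_rdm_mat),
                                        model_vecs, interest)
    E = lower_triangle(eeg_rdms)
    return _corr2_series(E, e1) - _corr2_series(E, e2)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each maximal run of True values."""
    runs, start = [], None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(mask) - start))
    return runs


@dataclass
class SignificanceWindows:
    observed: np.ndarray
    pointwise_threshold: np.ndarray
    cluster_length_threshold: float
    windows: pd.DataFrame  # start, length, p, significant
    n_permutations: int

    def significant_mask(self) -> np.ndarray:
        mask = np.zeros(self.observed.size, dtype=bool)
        for row in self.windows.itertuples():
            if row.significant:
                mask[row.start:row.start + row.length] = True
        return mask


def permutation_cluster_test(eeg_rdms: np.ndarray, fmri_rdm_mat: np.ndarray,
                             models: dict[str, np.ndarray], interest: str,
                             n_perm: int = 5000, alpha: float = 0.05,
                             seed: int = 0) -> SignificanceWindows:
    """Cluster-based permutation test of a commonality time course.

    Each permutation relabels the 8 cells of the EEG RDMs (one permutation
    applied consistently across time) and recomputes the commonality
    series. Points above the per-time (1 - alpha) quantile of permuted
    values form candidate windows; a window is significant when it is
    longer than the (1 - alpha) quantile of the permutations' maximal
    supra-threshold run lengths.
    """
    if n_perm < 500:
        raise ValueError("n_perm must be at least 500")
    eeg_rdms = np.asarray(eeg_rdms, dtype=float)
    n_t = eeg_rdms.shape[0]
    if n_t < 3:
        raise ValueError("series must have at least 3 time points")

    model_vecs = {m: lower_triangle(v) for m, v in models.items()}
    fmri_vec = lower_triangle(fmri_rdm_mat)
    e1, e2 = _commonality_residual_pair(fmri_vec, model_vecs, interest)
    observed = _corr2_series(lower_triangle(eeg_rdms), e1) \
        - _corr2_series(lower_triangle(eeg_rdms), e2)

    rng = np.random.default_rng(seed)
    perm_values = np.empty((n_perm, n_t))
    iu, ju = _TRIL
    for k in range(n_perm):
        perm = rng.permutation(N_CELLS)
        E = eeg_rdms[:, perm[iu], perm[ju]]
        perm_values[k] = _corr2_series(E, e1) - _corr2_series(E, e2)

    if alpha >= 1.0:
        thr = np.full(n_t, -np.inf)
        len_thr = 0.0
    else:
        thr = np.quantile(perm_values, 1 - alpha, axis=0, method="higher")
        max_lens = np.zeros(n_perm)
        for k in range(n_perm):
            runs = _runs_above(perm_values[k] > thr)
            max_lens[k] = max((length for _, length in runs), default=0)
        len_thr = float(np.quantile(max_lens, 1 - alpha, method="higher"))

    rows = []
    for start, length in _runs_above(observed > thr):
        if alpha >= 1.0:
            p, sig = 0.0, True
        else:
            p = float((1 + np.sum(max_lens >= length)) / (n_perm + 1))
            sig = length > len_thr
        rows.append({"start": start, "length": length, "p": p,
                     "significant": sig})
    windows = pd.DataFrame(rows, columns=["start", "length", "p", "significant"])
    return SignificanceWindows(observed=observed, pointwise_threshold=thr,
                               cluster_length_threshold=len_thr,
                               windows=windows, n_permutations=n_perm)
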