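"""Searchlight two-class decoding on run-wise betas.

A linear support vector machine (C = 1) is trained on the voxels of a moving
sphere and the balanced accuracy (mean of per-class recalls) of its test
predictions is assigned to the sphere's centre voxel. Observations are the
per-run cue or target betas, so every (cross-)validation scheme operates on
whole runs:

* ``decode_condition`` — attention vs. expectation on all cue betas, with
  leave-one-pseudorun-out CV (a pseudorun pairs temporally adjacent
  attention and expectation runs);
* ``decode_category`` — face-predicting vs. name-predicting cues within one
  condition, leave-one-run-out;
* ``cross_decode_between_conditions`` — category decoding trained on all of
  one condition's cue betas and tested on all of the other's (no CV; the two
  directions are averaged);
* ``cross_decode_cue_to_target`` — trained on three runs' cue betas, tested
  on the held-out run's target betas (direction fixed cue -> target);
* ``cross_decode_cue_pairs`` — trained on one face/name cue-shape pair and
  tested on the other, removing shape-specific perceptual information.

Sphere membership uses the strict inequality ``|v| < radius``, which yields
exactly 251 voxels at radius 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .design import CONDITIONS
from .glm import BetaMaps, CUE_LABELS, TARGET_LABELS


def searchlight_offsets(radius_voxels: float) -> np.ndarray:
    """All integer 3-vectors with Euclidean norm strictly below the radius.

    Lexicographically ordered; includes the centre. Radius 4 gives the
    251-voxel sphere used throughout.
    """
    if radius_voxels <= 0:
        raise ValueError("radius_voxels must be strictly positive")
    r = int(np.ceil(radius_voxels))
    offsets = [
        (x, y, z)
        for x, y, z in product(range(-r, r + 1), repeat=3)
        if x * x + y * y + z * z < radius_voxels ** 2
    ]
    return np.array(sorted(offsets), dtype=int)


@dataclass
class SearchlightSpec:
    """Sphere radius and analysis mask for a searchlight run."""

    radius_voxels: float = 4.0
    mask: np.ndarray | None = None  # boolean volume; None = whole grid
    offsets: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.offsets = searchlight_offsets(self.radius_voxels)


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of per-class recalls; chance is 0.5 for two classes regardless
    of class imbalance."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(y_true)
    if classes.size < 2:
        raise ValueError("every true class must be present")
    recalls = [np.mean(y_pred[y_true == c] == c) for c in classes]
    return float(np.mean(recalls))


@dataclass
class Observations:
    """Beta observations: ``X`` is (n_obs x n_voxels) with row metadata."""

    X: np.ndarray
    meta: pd.DataFrame


def cue_observations(maps: BetaMaps, trials: pd.DataFrame) -> Observations:
    """One observation per (run, cue regressor), labeled with the physical
    cue shape that carried that run's category prediction."""
    rows, X = [], []
    for run in maps.run_indices:
        run_trials = trials[trials.run_index == run]
        shape_of = dict(zip(run_trials.predicted_category, run_trials.cue_shape))
        for label in CUE_LABELS:
            category = label.split("_")[1]
            X.append(maps.beta(run, label))
            rows.append({"run": run, "condition": maps.runs[run].condition,
                         "epoch": "cue", "category": category,
                         "cue_shape": shape_of[category]})
    return Observations(X=np.array(X), meta=pd.DataFrame(rows))


def target_observations(maps: BetaMaps) -> Observations:
    rows, X = [], []
    for run in maps.run_indices:
        for label in TARGET_LABELS:
            _, category, cueing = label.split("_")
            X.append(maps.beta(run, label))
            rows.append({"run": run, "condition": maps.runs[run].condition,
                         "epoch": "target", "category": category,
                         "cueing": cueing})
    return Observations(X=np.array(X), meta=pd.DataFrame(rows))


@dataclass
class Fold:
    train: np.ndarray
    test: np.ndarray


def _check_folds(folds: list[Fold], y: np.ndarray) -> None:
    for fold in folds:
        overlap = np.intersect1d(fold.train, fold.test)
        if overlap.size:
            raise ValueError("train and test observations overlap within a fold")
        counts = pd.Series(y[fold.train]).value_counts()
        if counts.nunique() != 1 or len(counts) < 2:
            raise ValueError(f"training fold is not class balanced: {dict(counts)}")
        if np.unique(y[fold.test]).size < 2:
            raise ValueError("test fold must contain both classes")


@dataclass
class AccuracyMap:
    """Voxel grid of balanced accuracies (NaN outside the mask)."""

    data: np.ndarray
    scheme: str
    condition: str | None = None

    def mean_in(self, mask: np.ndarray) -> float:
        return float(np.nanmean(self.data[mask]))


def _sphere_table(mask: np.ndarray, offsets: np.ndarray
                  ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Flat centre indices and their in-mask sphere-member flat indices."""
    grid_shape = mask.shape
    centers = np.argwhere(mask)
    flat_mask = mask.ravel()
    center_flat, members = [], []
    for c in centers:
        pts = c[None, :] + offsets
        ok = np.all((pts >= 0) & (pts < np.array(grid_shape)), axis=1)
        flat = np.ravel_multi_index(pts[ok].T, grid_shape)
        flat = flat[flat_mask[flat]]
        center_flat.append(np.ravel_multi_index(c, grid_shape))
        members.append(flat)
    return np.array(center_flat), members


def decode_searchlight(obs: Observations, y: np.ndarray, folds: list[Fold],
                       sl: SearchlightSpec, grid_shape: tuple[int, int, int],
                       scheme: str = "custom",
                       condition: str | None = None) -> AccuracyMap:
    """Linear-SVM searchlight over the given folds.

    Features are mean-centered per fold using training-set means. Spheres
    with fewer than two in-mask voxels get NaN. Fold accuracies (balanced)
    are averaged per centre.
    """
    y = np.asarray(y)
    if not np.all(np.isfinite(obs.X)):
        raise ValueError("observations contain non-finite features")
    _check_folds(folds, y)
    mask = sl.mask if sl.mask is not None else np.ones(grid_shape, dtype=bool)
    center_flat, members = _sphere_table(mask, sl.offsets)

    out = np.full(grid_shape, np.nan).ravel()
    acc_sum = np.zeros(len(center_flat))
    for fold in folds:
        Xtr_full, Xte_full = obs.X[fold.train], obs.X[fold.test]
        mean = Xtr_full.mean(axis=0)
        Xtr_full = Xtr_full - mean
        Xte_full = Xte_full - mean
        ytr, yte = y[fold.train], y[fold.test]
        for i, cols in enumerate(members):
            if cols.size < 2:
                acc_sum[i] = np.nan
                continue
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(Xtr_full[:, cols], ytr)
            acc_sum[i] += balanced_accuracy(yte, clf.predict(Xte_full[:, cols]))
    out[center_flat] = acc_sum / len(folds)
    return AccuracyMap(data=out.reshape(grid_shape), scheme=scheme,
                       condition=condition)


# ---------------------------------------------------------------------------
# scheme builders


def decode_condition(maps: BetaMaps, trials: pd.DataFrame,
                     sl: SearchlightSpec) -> AccuracyMap:
    """Attention vs. expectation on cue betas, leave-one-pseudorun-out."""
    obs = cue_observations(maps, trials)
    y = obs.meta.condition.to_numpy()
    pseudorun = (obs.meta.run // 2).to_numpy()
    folds = [
        Fold(train=np.flatnonzero(pseudorun != p),
             test=np.flatnonzero(pseudorun == p))
        for p in np.unique(pseudorun)
    ]
    return decode_searchlight(obs, y, folds, sl, maps.grid_shape,
                              scheme="condition")


def decode_category(maps: BetaMaps, trials: pd.DataFrame, condition: str,
                    sl: SearchlightSpec) -> AccuracyMap:
    """Face-cue vs. name-cue within one condition, leave-one-run-out."""
    obs = cue_observations(maps, trials)
    keep = np.flatnonzero((obs.meta.condition == condition).to_numpy())
    obs = Observations(X=obs.X[keep], meta=obs.meta.iloc[keep].reset_index(drop=True))
    y = obs.meta.category.to_numpy()
    runs = obs.meta.run.to_numpy()
    folds = [
        Fold(train=np.flatnonzero(runs != r), test=np.flatnonzero(runs == r))
        for r in np.unique(runs)
    ]
    return decode_searchlight(obs, y, folds, sl, maps.grid_shape,
                              scheme="category", condition=condition)


def cross_decode_between_conditions(maps: BetaMaps, trials: pd.DataFrame,
                                    sl: SearchlightSpec) -> AccuracyMap:
    """Category decoding trained in one condition, tested in the other.

    No cross-validation: all of one condition's cue betas train, all of the
    other's test; the two directional maps are averaged.
    """
    obs = cue_observations(maps, trials)
    y = obs.meta.category.to_numpy()
    cond = obs.meta.condition.to_numpy()
    idx = {c: np.flatnonzero(cond == c) for c in CONDITIONS}
    for c, rows in idx.items():
        if np.unique(y[rows]).size < 2:
            raise ValueError(f"condition {c!r} lacks one of the two classes")
    folds = [Fold(train=idx["attention"], test=idx["expectation"]),
             Fold(train=idx["expectation"], test=idx["attention"])]
    return decode_searchlight(obs, y, folds, sl, maps.grid_shape,
                              scheme="cross-condition")


def cross_decode_cue_to_target(maps: BetaMaps, trials: pd.DataFrame,
                               condition: str, sl: SearchlightSpec
                               ) -> AccuracyMap:
    """Train on cue betas of three runs, test on the held-out run's targets."""
    cue = cue_observations(maps, trials)
    tgt = target_observations(maps)
    keep_c = np.flatnonzero((cue.meta.condition == condition).to_numpy())
    keep_t = np.flatnonzero((tgt.meta.condition == condition).to_numpy())
    X = np.vstack([cue.X[keep_c], tgt.X[keep_t]])
    meta = pd.concat([cue.meta.iloc[keep_c], tgt.meta.iloc[keep_t]],
                     ignore_index=True)
    obs = Observations(X=X, meta=meta)
    y = meta.category.to_numpy()
    runs = meta.run.to_numpy()
    is_cue = (meta.epoch == "cue").to_numpy()
    folds = [
        Fold(train=np.flatnonzero(is_cue & (runs != r)),
             test=np.flatnonzero(~is_cue & (runs == r)))
        for r in np.unique(runs)
    ]
    return decode_searchlight(obs, y, folds, sl, maps.grid_shape,
                              scheme="cue-target", condition=condition)


def default_shape_pairing(trials: pd.DataFrame) -> tuple[tuple[str, str], tuple[str, str]]:
    faces = sorted(trials.loc[trials.predicted_category == "face", "cue_shape"].unique())
    names = sorted(trials.loc[trials.predicted_category == "name", "cue_shape"].unique())
    return ((faces[0], names[0]), (faces[1], names[1]))


def cross_decode_cue_pairs(maps: BetaMaps, trials: pd.DataFrame,
                           condition: str, sl: SearchlightSpec,
                           shape_pairing: tuple[tuple[str, str], tuple[str, str]] | None = None,
                           ) -> AccuracyMap:
    """Train on one face/name cue-shape pair, test on the other.

    Because the training and test cues share no physical shape, transfer can
    only ride on the anticipated category, not on shape-specific perception.
    """
    if shape_pairing is None:
        shape_pairing = default_shape_pairing(trials)
    all_shapes = sorted(s for pair in shape_pairing for s in pair)
    if all_shapes != sorted(trials.cue_shape.unique()) or len(all_shapes) != 4:
        raise ValueError("shape_pairing must partition the four cue shapes")
    obs = cue_observations(maps, trials)
    keep = np.flatnonzero((obs.meta.condition == condition).to_numpy())
    obs = Observations(X=obs.X[keep], meta=obs.meta.iloc[keep].reset_index(drop=True))
    y = obs.meta.category.to_numpy()
    shape = obs.meta.cue_shape.to_numpy()
    in_pair = [np.flatnonzero(np.isin(shape, pair)) for pair in shape_pairing]
    folds = [Fold(train=in_pair[0], test=in_pair[1]),
             Fold(train=in_pair[1], test=in_pair[0])]
    return decode_searchlight(obs, y, folds, sl, maps.grid_shape,
                              scheme="cue-pair", condition=condition)
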