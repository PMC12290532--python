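"""Second-level inference and behavioral trimming.

Group maps are tested voxel-wise with one-sample t-tests (against 0.5 for
accuracy maps, 0 for difference maps; paired contrasts are one-sample tests
on participant-wise differences). Multiple comparisons over voxels use a
cluster-extent correction: voxels passing an uncorrected height threshold
(p < 0.001 by default) are grouped into 26-connected clusters, and cluster
sizes are referred to a max-cluster-size null distribution built by randomly
sign-flipping participants' (de-meaned) maps — a permutation analogue of
family-wise-error cluster correction. Region-of-interest extraction is
leave-one-subject-out (LOSO): each participant's ROI comes from the
second-level analysis of everyone else, preventing circular selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps
from statsmodels.stats.multitest import multipletests

#: 26-connectivity structure for 3-D cluster labeling
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class StatMap:
    t: np.ndarray
    p: np.ndarray
    df: int
    null_value: float
    tail: str = "greater"


def _one_sample_t(data: np.ndarray) -> tuple[np.ndarray, int]:
    """t statistic over axis 0, with zero-variance cells mapped to NaN."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    # sd of identical values may round to a denormal instead of 0
    degenerate = sd <= 1e-10 * np.abs(mean)
    t[degenerate | ~np.isfinite(t)] = np.nan
    return t, n - 1


def second_level_t_map(maps: np.ndarray, null_value: float = 0.0,
                       tail: str = "greater") -> StatMap:
    """Voxel-wise one-sample t-test of participant maps against ``null_value``.

    ``maps`` is (n_participants, *grid). Voxels where every participant has
    the identical value have zero variance; their t is NaN with a warning.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] < 3:
        raise ValueError("need at least 3 participants")
    t, df = _one_sample_t(maps - null_value)
    if np.any(np.isnan(t) & np.all(np.isfinite(maps), axis=0)):
        warnings.warn("zero-variance voxels produced undefined t values",
                      RuntimeWarning)
    if tail == "greater":
        p = sps.t.sf(t, df)
    elif tail == "two-sided":
        p = 2 * sps.t.sf(np.abs(t), df)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return StatMap(t=t, p=p, df=df, null_value=null_value, tail=tail)


@dataclass
class ClusterResult:
    """Supra-threshold clusters with permutation-corrected significance."""

    labels: np.ndarray            # 0 = background, 1..n = cluster id
    sizes: np.ndarray             # voxels per cluster (index = id - 1)
    corrected_p: np.ndarray
    significant: np.ndarray       # boolean per cluster
    voxel_threshold_t: float
    extent_threshold: float
    n_permutations: int = 0

    def significant_mask(self) -> np.ndarray:
        mask = np.zeros(self.labels.shape, dtype=bool)
        for cid in np.flatnonzero(self.significant):
            mask |= self.labels == cid + 1
        return mask

    def table(self) -> pd.DataFrame:
        rows = []
        for i, size in enumerate(self.sizes):
            com = ndimage.center_of_mass(self.labels == i + 1)
            rows.append({"cluster": i + 1, "size": int(size),
                         "corrected_p": float(self.corrected_p[i]),
                         "significant": bool(self.significant[i]),
                         "center": tuple(round(c, 1) for c in com)})
        return pd.DataFrame(rows)


def _max_cluster_size(t: np.ndarray, thr: float, tail: str) -> int:
    supra = (t > thr) if tail == "greater" else (np.abs(t) > thr)
    labels, n = ndimage.label(supra, structure=CONNECTIVITY_26)
    if n == 0:
        return 0
    return int(np.max(ndimage.sum_labels(np.ones_like(t), labels,
                                         np.arange(1, n + 1))))


def cluster_correct(maps: np.ndarray, null_value: float = 0.0,
                    voxel_p: float = 0.001, alpha: float = 0.05,
                    n_perm: int = 1000, tail: str = "greater",
                    seed: int = 0) -> ClusterResult:
    """Cluster-extent correction by sign-flip permutation.

    Height threshold: the t value with one-sided (or two-sided) uncorrected
    ``voxel_p``. Null: each permutation flips the sign of each participant's
    de-meaned map independently, recomputes the t map and records the
    largest supra-threshold 26-connected cluster. A cluster is significant
    when its permutation p value ((1 + #{null >= size}) / (n_perm + 1)) is
    at most ``alpha``; the (1 - alpha) null quantile is reported as the
    extent threshold.
    """
    if n_perm < 500:
        raise ValueError("n_perm must be at least 500")
    maps = np.asarray(maps, dtype=float)
    data = maps - null_value
    t, df = _one_sample_t(data)
    if tail == "greater":
        thr = sps.t.isf(voxel_p, df)
        supra = t > thr
    elif tail == "two-sided":
        thr = sps.t.isf(voxel_p / 2, df)
        supra = np.abs(t) > thr
    else:
        raise ValueError(f"unknown tail {tail!r}")

    labels, n_clusters = ndimage.label(supra, structure=CONNECTIVITY_26)
    sizes = (ndimage.sum_labels(np.ones_like(t), labels,
                                np.arange(1, n_clusters + 1)).astype(int)
             if n_clusters else np.zeros(0, dtype=int))

    rng = np.random.default_rng(seed)
    n_part = data.shape[0]
    null_sizes = np.zeros(n_perm)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_part)
        t_perm, _ = _one_sample_t(data * signs.reshape((-1,) + (1,) * (data.ndim - 1)))
        null_sizes[i] = _max_cluster_size(t_perm, thr, tail)

    extent = float(np.quantile(null_sizes, 1 - alpha, method="higher"))
    corrected_p = np.array([
        (1 + np.sum(null_sizes >= s)) / (n_perm + 1) for s in sizes
    ])
    significant = corrected_p <= alpha if n_clusters else np.zeros(0, dtype=bool)
    return ClusterResult(labels=labels, sizes=sizes, corrected_p=corrected_p,
                         significant=significant, voxel_threshold_t=float(thr),
                         extent_threshold=extent, n_permutations=n_perm)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    flags, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return flags


def loso_rois(maps: np.ndarray, null_value: float = 0.0,
              voxel_p: float = 0.001, alpha: float = 0.05,
              n_perm: int = 1000, tail: str = "greater",
              seed: int = 0) -> list[np.ndarray]:
    """Leave-one-subject-out ROI masks.

    For each participant, the cluster-corrected second-level analysis is
    repeated on the other N-1 participants' maps, and the union of their
    significant clusters (on the shared synthetic grid) is that
    participant's ROI. Folds with no significant cluster yield an empty
    mask with a warning.
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if n < 4:
        raise ValueError("need at least 4 participants for LOSO ROIs")
    rois = []
    for i in range(n):
        others = np.delete(maps, i, axis=0)
        res = cluster_correct(others, null_value=null_value, voxel_p=voxel_p,
                              alpha=alpha, n_perm=n_perm, tail=tail, seed=seed)
        roi = res.significant_mask()
        if not roi.any():
            warnings.warn(f"LOSO fold {i}: no significant cluster, empty ROI",
                          RuntimeWarning)
        rois.append(roi)
    return rois


def conjunction_map(a: ClusterResult | np.ndarray,
                    b: ClusterResult | np.ndarray) -> np.ndarray:
    """Voxel-wise AND of two binarized significant maps."""
    ma = a.significant_mask() if isinstance(a, ClusterResult) else np.asarray(a, bool)
    mb = b.significant_mask() if isinstance(b, ClusterResult) else np.asarray(b, bool)
    if ma.shape != mb.shape:
        raise ValueError("conjunction requires identical grids")
    return ma & mb


def trim_rts(behavior: pd.DataFrame,
             group_cols: tuple[str, ...] = ("condition",),
             n_sd: float = 2.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop trials whose RT is beyond mean +/- ``n_sd`` SD of its cell.

    Cells are defined by ``group_cols`` (per participant x condition when a
    ``participant`` column is present and included). Statistics come from
    the untrimmed cell in a single pass; cells with fewer than 3 trials pass
    through untrimmed with a warning. Returns the trimmed table and a
    per-cell report of discarded fractions.
    """
    behavior = behavior.reset_index(drop=True)
    keep = np.ones(len(behavior), dtype=bool)
    report_rows = []
    for key, cell in behavior.groupby(list(group_cols)):
        if len(cell) < 3:
            warnings.warn(f"cell {key}: fewer than 3 trials, not trimmed",
                          RuntimeWarning)
            report_rows.append({"cell": key, "n": len(cell), "n_discarded": 0,
                                "fraction_discarded": 0.0})
            continue
        mean = cell.rt_ms.mean()
        sd = cell.rt_ms.std(ddof=1)
        out = np.abs(cell.rt_ms - mean) > n_sd * sd
        keep[cell.index[out]] = False
        report_rows.append({"cell": key, "n": len(cell),
                            "n_discarded": int(out.sum()),
                            "fraction_discarded": float(out.mean())})
    return behavior[keep].copy(), pd.DataFrame(report_rows)
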