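"""Voxel selectivity ranking: does cue-epoch tuning generalize to targets?

For one condition (attention or expectation) and ROI there are 8 cells per
voxel — category (face/name) crossed with the condition's four runs. Each
voxel's cells are ordered from least to most cue-epoch activity, the same
order is applied to that voxel's target-epoch betas, the reordered vectors
are averaged over the ROI's voxels, and an ordinary least-squares line over
rank positions 1..8 summarizes the result. A positive slope means voxels
most responsive to a cell during anticipation are also most responsive to it
during target perception — stable tuning. Group inference is a right-tailed
one-sample t-test of slopes against 0 per ROI and condition (FDR-corrected),
followed by a paired two-tailed comparison of conditions where at least one
is significant. A control re-fits the slope on the first 7 ranks only, which
drops the top-activity cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .glm import BetaMaps
from .stats import fdr_bh

T_CAP = 1e6


def condition_rank_inputs(maps: BetaMaps, condition: str,
                          roi_mask: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Cue and matched target beta matrices, shape (8 cells x n_roi_voxels).

    Cells are category x run for the condition's four runs; the target value
    of a category collapses its cued and uncued regressors.
    """
    idx = np.flatnonzero(np.asarray(roi_mask).ravel())
    cue_rows, tgt_rows = [], []
    for run in maps.runs_of_condition(condition):
        for category in ("face", "name"):
            cue_rows.append(maps.beta(run, f"cue_{category}")[idx])
            tgt = (maps.beta(run, f"target_{category}_cued")[idx]
                   + maps.beta(run, f"target_{category}_uncued")[idx]) / 2.0
            tgt_rows.append(tgt)
    return np.array(cue_rows), np.array(tgt_rows)


def slope_over_ranks(values: np.ndarray, k: int | None = None) -> float:
    """OLS slope of ``values`` against rank positions 1..k (unit spacing)."""
    v = np.asarray(values, dtype=float)
    if k is not None:
        v = v[:k]
    ranks = np.arange(1, v.size + 1, dtype=float)
    return float(np.polyfit(ranks, v, 1)[0])


@dataclass
class RankingEntry:
    ranked: np.ndarray
    slope: float
    condition: str


def rank_and_slope(cue: np.ndarray, target: np.ndarray,
                   condition: str = "", k: int | None = None) -> RankingEntry:
    """Order each voxel's cells by cue activity, apply to targets, average.

    ``cue`` and ``target`` are (n_cells x n_voxels). Sorting is stable, so
    tied cue betas break deterministically by cell index. The ROI-average of
    the reordered target vectors and its OLS slope over ranks are returned.
    """
    cue = np.asarray(cue, dtype=float)
    target = np.asarray(target, dtype=float)
    if cue.shape != target.shape:
        raise ValueError("cue and target matrices must share shape")
    order = np.argsort(cue, axis=0, kind="stable")
    reordered = np.take_along_axis(target, order, axis=0)
    ranked = reordered.mean(axis=1)
    return RankingEntry(ranked=ranked, slope=slope_over_ranks(ranked, k=k),
                        condition=condition)


def participant_slopes(maps: BetaMaps, roi_masks: dict[str, np.ndarray],
                       k: int | None = None) -> pd.DataFrame:
    """Slope per ROI x condition for one participant's beta maps."""
    rows = []
    for roi, mask in roi_masks.items():
        for condition in ("attention", "expectation"):
            cue, tgt = condition_rank_inputs(maps, condition, mask)
            entry = rank_and_slope(cue, tgt, condition=condition, k=k)
            rows.append({"roi": roi, "condition": condition,
                         "slope": entry.slope})
    return pd.DataFrame(rows)


def _safe_one_sample_t(x: np.ndarray) -> tuple[float, float]:
    """Right-tailed one-sample t against 0, capping zero-variance cases."""
    x = np.asarray(x, dtype=float)
    if np.std(x, ddof=1) == 0:
        warnings.warn("zero-variance slopes: t capped", RuntimeWarning)
        if x.mean() == 0:
            return 0.0, 1.0
        return (T_CAP if x.mean() > 0 else -T_CAP,
                0.0 if x.mean() > 0 else 1.0)
    res = sps.ttest_1samp(x, 0.0, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def ranking_group_tests(slopes: pd.DataFrame, q: float = 0.05
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group tests over participants' slopes.

    ``slopes`` has columns participant, roi, condition, slope. Returns the
    per-ROI x condition one-sample table (t, p, FDR flag over the whole
    family) and the paired attention-vs-expectation table restricted to ROIs
    where at least one condition survived FDR.
    """
    if slopes.participant.nunique() < 3:
        raise ValueError("need at least 3 participants")
    rows = []
    for (roi, condition), cell in slopes.groupby(["roi", "condition"]):
        t, p = _safe_one_sample_t(cell.slope.to_numpy())
        rows.append({"roi": roi, "condition": condition,
                     "mean_slope": float(cell.slope.mean()), "t": t, "p": p})
    table = pd.DataFrame(rows)
    table["significant"] = fdr_bh(table.p.to_numpy(), q=q)

    paired_rows = []
    wide = slopes.pivot_table(index=["roi", "participant"], columns="condition",
                              values="slope").reset_index()
    for roi in table.roi.unique():
        if not table.loc[table.roi == roi, "significant"].any():
            continue
        sub = wide[wide.roi == roi]
        res = sps.ttest_rel(sub["attention"], sub["expectation"])
        paired_rows.append({
            "roi": roi,
            "mean_difference": float((sub["attention"] - sub["expectation"]).mean()),
            "t": float(res.statistic), "p": float(res.pvalue),
        })
    paired = pd.DataFrame(paired_rows,
                          columns=["roi", "mean_difference", "t", "p"])
    if len(paired):
        paired["significant"] = fdr_bh(paired.p.to_numpy(), q=q)
    else:
        paired["significant"] = pd.Series(dtype=bool)
    return table, paired
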