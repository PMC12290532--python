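"""Synthetic behavior: log-normal reaction times with an expectation-only
cueing benefit, and Bernoulli accuracy.

The planted benefit shifts cued trials faster and uncued trials slower by
half the benefit each, and only in expectation blocks — in attention blocks
the cue carries no probabilistic information about the target category, so no
RT benefit is planted there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class BehaviorEffectSpec:
    median_rt_ms: float = 650.0
    rt_sigma: float = 0.25          # log-scale SD of the log-normal RT
    cueing_benefit_ms: float = 25.0  # cued-uncued mean difference, expectation only
    accuracy: float = 0.93

    def __post_init__(self) -> None:
        if not np.isfinite(self.cueing_benefit_ms):
            raise ValueError("cueing_benefit_ms must be finite")
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


def generate_behavior(trials: pd.DataFrame,
                      spec: BehaviorEffectSpec = BehaviorEffectSpec(),
                      seed: int = 0) -> pd.DataFrame:
    """Per-trial RT (ms) and correctness for a trial table."""
    rng = np.random.default_rng(seed)
    n = len(trials)
    rt = spec.median_rt_ms * np.exp(spec.rt_sigma * rng.standard_normal(n))
    is_exp = (trials.condition == "expectation").to_numpy()
    cued = (trials.cueing == "cued").to_numpy()
    shift = np.where(is_exp & cued, -spec.cueing_benefit_ms / 2, 0.0)
    shift = shift + np.where(is_exp & ~cued, spec.cueing_benefit_ms / 2, 0.0)
    out = trials.copy()
    out["rt_ms"] = rt + shift
    out["correct"] = rng.random(n) < spec.accuracy
    return out


def cueing_effect(behavior: pd.DataFrame, condition: str = "expectation"
                  ) -> dict[str, float]:
    """Cued-vs-uncued RT summary in one condition (Wilcoxon on cell means is
    left to the caller when multiple participants are available)."""
    sub = behavior[behavior.condition == condition]
    cued = sub.loc[sub.cueing == "cued", "rt_ms"]
    uncued = sub.loc[sub.cueing == "uncued", "rt_ms"]
    t, p = stats.ttest_ind(uncued, cued)
    return {
        "cued_mean_ms": float(cued.mean()),
        "uncued_mean_ms": float(uncued.mean()),
        "benefit_ms": float(uncued.mean() - cued.mean()),
        "t": float(t), "p": float(p),
    }
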