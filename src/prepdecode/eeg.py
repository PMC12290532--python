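"""Synthetic EEG epochs with a ramping anticipatory category signal.

Epochs are channel x time matrices spanning -200 ms to 1550 ms around cue
onset (1550 ms is target onset in the EEG session, where cues and targets
were briefly flashed and intervals were not jittered). Each epoch belongs to
one of 8 cells crossing condition (attention/expectation), predicted category
(face/name) and cue shape (2 per category). Three planted channel patterns
shape the signal:

* *category*: a linear ramp from cue onset to target onset, so pairwise
  category distances grow monotonically over the interval;
* *condition*: sustained from cue onset;
* *cue shape*: an early transient (Gaussian bump around 150 ms).

White Gaussian sensor noise is added per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CATEGORIES, CONDITIONS, DEFAULT_CUE_SHAPES

#: canonical cell order used by every RDM: condition x category x shape index
CELL_ORDER: tuple[tuple[str, str, int], ...] = tuple(
    (cond, cat, idx)
    for cond in CONDITIONS for cat in CATEGORIES for idx in (1, 2)
)


def cell_labels() -> pd.DataFrame:
    """The 8 canonical cells with their physical cue shapes."""
    rows = []
    for cond, cat, idx in CELL_ORDER:
        pool = DEFAULT_CUE_SHAPES[:2] if cat == "face" else DEFAULT_CUE_SHAPES[2:]
        rows.append({"condition": cond, "category": cat,
                     "shape_index": idx, "cue_shape": pool[idx - 1]})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EEGEffectSpec:
    """Planted EEG effect structure (amplitudes in sensor-noise SD units)."""

    n_channels: int = 30
    tmin_ms: float = -200.0
    tmax_ms: float = 1550.0
    dt_ms: float = 25.0
    ramp_amplitude: float = 2.0
    condition_amplitude: float = 1.0
    shape_amplitude: float = 0.5
    shape_latency_ms: float = 150.0
    shape_width_ms: float = 50.0
    noise_sd: float = 1.0
    trials_per_cell: int = 24

    def times_ms(self) -> np.ndarray:
        return np.arange(self.tmin_ms, self.tmax_ms + self.dt_ms / 2, self.dt_ms)


@dataclass
class SyntheticEEG:
    """Labeled single-trial epochs: ``data`` is (n_epochs, n_channels, n_times)."""

    data: np.ndarray
    times_ms: np.ndarray
    labels: pd.DataFrame

    def cell_index(self) -> np.ndarray:
        """Index of each epoch into the canonical 8-cell order."""
        key = {cell: i for i, cell in enumerate(CELL_ORDER)}
        return np.array([
            key[(r.condition, r.category, r.shape_index)]
            for r in self.labels.itertuples()
        ])


def generate_eeg(effects: EEGEffectSpec = EEGEffectSpec(),
                 seed: int = 0) -> SyntheticEEG:
    """Generate labeled epochs for all 8 condition x category x shape cells."""
    times = effects.times_ms()
    if times[0] > 0 or times[-1] < 1550.0 - effects.dt_ms:
        raise ValueError("time axis must cover cue onset through 1550 ms")
    rng = np.random.default_rng(seed)
    nc, nt = effects.n_channels, times.size

    cat_pattern = rng.standard_normal(nc)
    cond_pattern = rng.standard_normal(nc)
    shape_patterns = {s: rng.standard_normal(nc) for s in DEFAULT_CUE_SHAPES}

    post = times >= 0
    ramp = np.where(post, np.clip(times / effects.tmax_ms, 0.0, 1.0), 0.0)
    sustained = post.astype(float)
    bump = np.exp(-0.5 * ((times - effects.shape_latency_ms)
                          / effects.shape_width_ms) ** 2) * post

    cells = cell_labels()
    epochs, rows = [], []
    for row in cells.itertuples():
        cat_sign = 1.0 if row.category == "face" else -1.0
        cond_sign = 1.0 if row.condition == "attention" else -1.0
        mean = (effects.ramp_amplitude * cat_sign * np.outer(cat_pattern, ramp)
                + effects.condition_amplitude * cond_sign
                * np.outer(cond_pattern, sustained)
                + effects.shape_amplitude
                * np.outer(shape_patterns[row.cue_shape], bump))
        for _ in range(effects.trials_per_cell):
            epochs.append(mean + effects.noise_sd * rng.standard_normal((nc, nt)))
            rows.append({"condition": row.condition, "category": row.category,
                         "shape_index": row.shape_index,
                         "cue_shape": row.cue_shape})
    return SyntheticEEG(data=np.stack(epochs), times_ms=times,
                        labels=pd.DataFrame(rows))
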