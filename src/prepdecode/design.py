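"""Experimental design generation for the cue-target anticipation task.

The task crosses two block types. In *attention* blocks the cue signals which
stimulus category (face or name) is relevant for the gender judgment; the
target belongs to the cued category on exactly half the trials. In
*expectation* blocks the cue predicts the likely target category with 75%
validity while both categories remain task relevant; the marginal frequency of
each target category is still 50%.

Each session has 8 runs of 48 trials, alternating attention/expectation. Four
cue shapes are used throughout: two mapped to faces and two to names, with the
mapping fixed for the whole experiment. A run shows exactly one face-predictive
and one name-predictive shape, and the four face/name shape pairings rotate
across a condition's runs so that each face shape co-occurs once with each name
shape. Cue (500 ms) and target (500 ms) are separated by a cue-target interval
(CTI) jittered on a 700 ms grid from 2500 to 6000 ms; the inter-trial interval
uses the same grid. Jitters are exactly counterbalanced within each run, so
the per-run mean is 4250 ms, the mean trial lasts 9.5 s and a default run
7.6 min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("attention", "expectation")
CATEGORIES = ("face", "name")

#: CTI/ITI jitter grid in ms: 2500-6000 in 700 ms steps (mean 4250).
JITTER_GRID_MS = tuple(range(2500, 6001, 700))

DEFAULT_CUE_SHAPES = ("circle", "square", "diamond", "drop")

#: (face-shape index, name-shape index) pairings cycled over a condition's runs
#: so each face shape appears with each name shape equally often.
_SHAPE_PAIRINGS = ((0, 0), (1, 1), (0, 1), (1, 0))


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the factorial cue-target design.

    ``cue_shapes`` lists four shape identifiers; the first two predict faces,
    the last two predict names, and the mapping is constant across the
    experiment. ``expectation_validity`` is the proportion of expectation
    trials whose target matches the cued category (attention is always 0.5).
    """

    n_runs: int = 8
    trials_per_run: int = 48
    first_condition: str = "attention"
    cue_shapes: tuple[str, str, str, str] = DEFAULT_CUE_SHAPES
    expectation_validity: float = 0.75
    cue_ms: int = 500
    target_ms: int = 500
    jitter_grid_ms: tuple[int, ...] = JITTER_GRID_MS
    tr_ms: float = 1730.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.first_condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.first_condition!r}")
        if len(self.cue_shapes) != 4 or len(set(self.cue_shapes)) != 4:
            raise ValueError("cue_shapes must be 4 distinct identifiers")
        if not 0.0 <= self.expectation_validity <= 1.0:
            raise ValueError("expectation_validity must lie in [0, 1]")

    @property
    def face_shapes(self) -> tuple[str, str]:
        return self.cue_shapes[:2]

    @property
    def name_shapes(self) -> tuple[str, str]:
        return self.cue_shapes[2:]

    def shape_for(self, category: str, shape_index: int) -> str:
        """Physical shape for a (category, within-category index 0/1) cell."""
        pool = self.face_shapes if category == "face" else self.name_shapes
        return pool[shape_index]

    def run_condition(self, run_index: int) -> str:
        offset = CONDITIONS.index(self.first_condition)
        return CONDITIONS[(run_index + offset) % 2]


TRIAL_COLUMNS = [
    "run_index", "condition", "cue_shape", "predicted_category",
    "target_category", "cueing", "cue_onset_ms", "cti_ms",
    "target_onset_ms", "iti_ms",
]


def _validity_for(spec: DesignSpec, condition: str) -> float:
    return spec.expectation_validity if condition == "expectation" else 0.5


def _check_cell_counts(spec: DesignSpec) -> None:
    n = spec.trials_per_run
    if n % 8 != 0:
        raise ValueError(
            f"trials_per_run={n} is not divisible by 8: the "
            "cue-shape x target-category x cueing cells cannot balance exactly"
        )
    per_cue = n // 2
    for condition in CONDITIONS:
        validity = _validity_for(spec, condition)
        n_valid = validity * per_cue
        if abs(n_valid - round(n_valid)) > 1e-9:
            raise ValueError(
                f"{condition} runs need {validity} x {per_cue} = {n_valid} "
                "valid trials per cue, which is not an integer"
            )


def _run_jitters(rng: np.random.Generator, n: int, grid: tuple[int, ...]) -> np.ndarray:
    """One jitter per trial: an exact permutation of the grid when possible."""
    grid_arr = np.asarray(grid)
    if n % len(grid_arr) == 0:
        values = np.tile(grid_arr, n // len(grid_arr))
        return rng.permutation(values)
    return rng.choice(grid_arr, size=n, replace=True)


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Generate the trial table of one synthetic session.

    Returns a DataFrame with one row per trial (columns ``TRIAL_COLUMNS``).
    All counterbalancing constraints are enforced exactly: per run each of the
    two cue shapes appears on half the trials, each target category appears on
    half the trials, and within each cue's trials the target matches the
    prediction on exactly ``validity`` of them (75% in expectation, 50% in
    attention at defaults). Deterministic given ``spec.seed``.
    """
    _check_cell_counts(spec)
    rng = np.random.default_rng(spec.seed)
    per_cue = spec.trials_per_run // 2
    rows: list[dict] = []
    condition_run_counter = {c: 0 for c in CONDITIONS}

    for run_index in range(spec.n_runs):
        condition = spec.run_condition(run_index)
        pairing = _SHAPE_PAIRINGS[condition_run_counter[condition] % len(_SHAPE_PAIRINGS)]
        condition_run_counter[condition] += 1
        shape_of = {
            "face": spec.face_shapes[pairing[0]],
            "name": spec.name_shapes[pairing[1]],
        }
        validity = _validity_for(spec, condition)
        n_valid = round(validity * per_cue)

        trial_cells: list[tuple[str, str]] = []
        for predicted in CATEGORIES:
            other = "name" if predicted == "face" else "face"
            trial_cells += [(predicted, predicted)] * n_valid
            trial_cells += [(predicted, other)] * (per_cue - n_valid)
        order = rng.permutation(len(trial_cells))
        ctis = _run_jitters(rng, spec.trials_per_run, spec.jitter_grid_ms)
        itis = _run_jitters(rng, spec.trials_per_run, spec.jitter_grid_ms)

        t = 0.0
        for i, cell_idx in enumerate(order):
            predicted, target = trial_cells[cell_idx]
            cti = float(ctis[i])
            target_onset = t + spec.cue_ms + cti
            rows.append({
                "run_index": run_index,
                "condition": condition,
                "cue_shape": shape_of[predicted],
                "predicted_category": predicted,
                "target_category": target,
                "cueing": "cued" if target == predicted else "uncued",
                "cue_onset_ms": t,
                "cti_ms": cti,
                "target_onset_ms": target_onset,
                "iti_ms": float(itis[i]),
            })
            t = target_onset + spec.target_ms + float(itis[i])

    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def run_duration_ms(trials: pd.DataFrame, run_index: int, target_ms: float = 500.0) -> float:
    run = trials[trials.run_index == run_index]
    last = run.iloc[-1]
    return float(last.target_onset_ms + target_ms + last.iti_ms)


def design_report(trials: pd.DataFrame, spec: DesignSpec | None = None) -> dict:
    """Structural summary of a trial table.

    Reports the constants a session realizes by construction: trial counts,
    mean CTI/ITI, mean trial duration, mean run duration, and the realized
    cue validity per condition (percentage of trials whose target category
    matches the cued one).
    """
    spec = spec or DesignSpec()
    durations = [
        run_duration_ms(trials, r, spec.target_ms) for r in trials.run_index.unique()
    ]
    report = {
        "n_trials": int(len(trials)),
        "n_runs": int(trials.run_index.nunique()),
        "mean_cti_ms": float(trials.cti_ms.mean()),
        "mean_iti_ms": float(trials.iti_ms.mean()),
        "mean_trial_duration_s": float(
            (spec.cue_ms + trials.cti_ms + spec.target_ms + trials.iti_ms).mean() / 1000.0
        ),
        "mean_run_duration_min": float(np.mean(durations) / 60000.0),
    }
    for condition in CONDITIONS:
        sub = trials[trials.condition == condition]
        match = (sub.target_category == sub.predicted_category).mean()
        report[f"{condition}_validity_pct"] = float(100.0 * match)
    return report
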