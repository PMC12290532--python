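"""Readers/writers: NIfTI volumes, BIDS-style events tables, YAML configs,
and the EEG epoch array + JSON sidecar convention."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .design import TRIAL_COLUMNS
from .eeg import SyntheticEEG


def write_nifti(path: str | Path, data: np.ndarray,
                affine: np.ndarray | None = None,
                voxel_size_mm: float = 3.0) -> Path:
    """Write a 3-D/4-D grid as NIfTI-1, recording the voxel size."""
    data = np.asarray(data)
    if data.ndim not in (3, 4):
        raise ValueError("expected a 3-D or 4-D grid")
    if affine is None:
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((voxel_size_mm,) * 3 + ((1.0,) if data.ndim == 4 else ()))
    path = Path(path)
    nib.save(img, path)
    return path


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI-1 file; data is returned with its on-disk dtype."""
    path = Path(path)
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise IOError(f"malformed NIfTI file {path}: {exc}") from exc
    return data, img.affine


def trials_to_events(trials: pd.DataFrame) -> pd.DataFrame:
    """BIDS-style events table: onset/duration in seconds, one row per trial.

    ``trial_type`` encodes condition, predicted category and cueing; every
    original trial column rides along so the table round-trips losslessly.
    """
    events = pd.DataFrame({
        "onset": trials.cue_onset_ms / 1000.0,
        "duration": (trials.target_onset_ms + 500.0 - trials.cue_onset_ms) / 1000.0,
        "trial_type": (trials.condition + "_" + trials.predicted_category
                       + "_" + trials.cueing),
    })
    for col in TRIAL_COLUMNS:
        events[col] = trials[col].to_numpy()
    return events


def write_events(path: str | Path, trials: pd.DataFrame) -> Path:
    path = Path(path)
    trials_to_events(trials).to_csv(path, sep="\t", index=False,
                                    float_format="%.17g")
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an events TSV back into a trial table."""
    events = pd.read_csv(path, sep="\t")
    for col in ("onset", "duration"):
        if col not in events.columns:
            raise ValueError(f"events file {path} lacks required column {col!r}")
    if len(events) == 0:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    per_run = events.groupby("run_index").onset
    if (per_run.apply(lambda s: not s.is_monotonic_increasing)).any():
        warnings.warn(f"{path}: onsets are not monotonically increasing "
                      "within runs", RuntimeWarning)
    trials = events[TRIAL_COLUMNS].copy()
    trials["run_index"] = trials.run_index.astype(np.int64)
    for col in ("cue_onset_ms", "cti_ms", "target_onset_ms", "iti_ms"):
        trials[col] = trials[col].astype(np.float64)
    return trials


def write_eeg(path_prefix: str | Path, eeg: SyntheticEEG) -> tuple[Path, Path]:
    """EEG epochs as a plain ``.npy`` array plus a JSON label sidecar."""
    prefix = Path(path_prefix)
    npy = prefix.with_suffix(".npy")
    np.save(npy, eeg.data)
    sidecar = prefix.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "times_ms": eeg.times_ms.tolist(),
        "n_channels": int(eeg.data.shape[1]),
        "labels": eeg.labels.to_dict(orient="records"),
    }, indent=1))
    return npy, sidecar


def read_eeg(path_prefix: str | Path) -> SyntheticEEG:
    prefix = Path(path_prefix)
    data = np.load(prefix.with_suffix(".npy"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return SyntheticEEG(data=data, times_ms=np.asarray(meta["times_ms"]),
                        labels=pd.DataFrame(meta["labels"]))


def save_config(path: str | Path, config: dict) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config, sort_keys=False))
    return path


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
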