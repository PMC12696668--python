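"""File formats: CSV trial tables, HDF5 waveform stores, NIfTI volumes,
YAML configs and JSON reports.

The trial table is plain CSV with a documented column dictionary (see
``TRIAL_COLUMNS``); waveforms go into a single HDF5 container as one
(n_trials, n_samples) dataset indexed by the table's ``trial_id``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .focus import Volume

__all__ = [
    "TRIAL_COLUMNS",
    "write_trials", "read_trials",
    "write_waveforms", "read_waveforms",
    "write_volume", "read_volume",
    "write_yaml", "read_yaml",
    "write_json_report", "read_json_report",
]

#: column dictionary for the trial table CSV
TRIAL_COLUMNS = {
    "trial_id": "unique integer id; index into the waveform store",
    "participant": "0-based participant index",
    "session": "1 or 2 (chronological session)",
    "condition": "verum | sham",
    "timepoint": "Baseline | T5 | T30 | T60",
    "muscle": "FDI | APB | ADM (EMG channel)",
    "pulse_type": "single | TS | SICI | ICF",
    "acq_block": "single-pulse vs interleaved paired-pulse acquisition block",
    "mep_pp": "peak-to-peak MEP amplitude, mV",
    "pre_rms": "RMS of the 100 ms pre-stimulus window, mV",
    "pre_pp": "peak-to-peak of the pre-stimulus window, mV",
    "amp_true": "generator ground truth amplitude, mV (synthetic only)",
    "pre_rms_true": "generator ground truth pre-stimulus RMS (synthetic only)",
    "is_outlier_gt": "ground truth: injected amplitude outlier",
    "is_precontraction_gt": "ground truth: injected pre-contraction",
    "is_noise_gt": "ground truth: injected broadband noise",
    "flag_outlier": "excluded by the Grubbs rule",
    "flag_precontraction": "excluded by the pre-contraction rule",
    "flag_noise": "excluded by the noise rule",
    "excluded": "any exclusion rule fired",
}

_BOOL_COLS = [c for c in TRIAL_COLUMNS
              if c.startswith(("is_", "flag_")) or c == "excluded"]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "trial_id" not in df.columns:
        raise ValueError(f"{path}: not a trial table (no trial_id column)")
    for c in _BOOL_COLS:
        if c in df.columns:
            df[c] = df[c].astype(bool)
    return df


def write_waveforms(
    waveforms: np.ndarray, trial_ids: np.ndarray, sampling_rate: float,
    stimulus_sample: int, path: str | Path,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("waveforms", data=np.asarray(waveforms, np.float32),
                         compression="gzip", compression_opts=4)
        f.create_dataset("trial_id", data=np.asarray(trial_ids, np.int64))
        f.attrs["sampling_rate_hz"] = float(sampling_rate)
        f.attrs["stimulus_sample"] = int(stimulus_sample)
        f.attrs["units"] = "mV"


def read_waveforms(path: str | Path) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Returns (waveforms, trial_ids, sampling_rate, stimulus_sample)."""
    with h5py.File(path, "r") as f:
        if "waveforms" not in f or "trial_id" not in f:
            raise ValueError(f"{path}: not a waveform store")
        wf = f["waveforms"][()]
        ids = f["trial_id"][()]
        sr = float(f.attrs["sampling_rate_hz"])
        stim = int(f.attrs["stimulus_sample"])
    return wf, ids, sr, stim


def write_volume(volume: Volume, path: str | Path) -> None:
    nib.save(volume.to_nifti(), str(path))


def read_volume(path: str | Path, as_mask: bool = False) -> Volume:
    return Volume.from_nifti(nib.load(str(path)), as_mask=as_mask)


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=False)


def read_yaml(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_json_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        json.dump(report, f, indent=2, cls=_NumpyEncoder)


def read_json_report(path: str | Path) -> dict:
    with open(path) as f:
        return json.load(f)
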