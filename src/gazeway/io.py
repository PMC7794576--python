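"""Plain-text readers and writers.

Everything moves through tidy CSV tables so intermediate results can
be inspected, diffed and fed back into individual pipeline stages.
Column contracts:

* vehicle log:  t, x, z, yaw [, mode, trial, participant]
* gaze log:     t, screen_x, screen_y, confidence [, labels]
* TH table:     participant, mode, trial, t, time_into_trial_s, th_s,
                ref_arc_m, angular_error_deg, excluded, reason

YAML config files hold the dataclass fields of TrackConfig,
CameraModel and SynthConfig by name; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .camera import CameraModel
from .synth import SynthConfig
from .track import TrackConfig

VEHICLE_COLUMNS = ["t", "x", "z", "yaw"]
GAZE_COLUMNS = ["t", "screen_x", "screen_y", "confidence"]


def _read_csv(path, required) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_vehicle_csv(path) -> pd.DataFrame:
    return _read_csv(path, VEHICLE_COLUMNS)


def read_gaze_csv(path) -> pd.DataFrame:
    return _read_csv(path, GAZE_COLUMNS)


def read_th_table(path) -> pd.DataFrame:
    return _read_csv(path, ["time_into_trial_s", "th_s", "excluded"])


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def _load_dataclass(cls, path):
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - names
    if unknown:
        raise ValueError(f"{path}: unknown {cls.__name__} keys {sorted(unknown)}")
    return cls(**raw)


def load_track_config(path) -> TrackConfig:
    return _load_dataclass(TrackConfig, path)


def load_camera_config(path) -> CameraModel:
    return _load_dataclass(CameraModel, path)


def load_synth_config(path) -> SynthConfig:
    return _load_dataclass(SynthConfig, path)


def dump_config(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(obj), fh, sort_keys=True)
    return path
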