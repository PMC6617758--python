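"""CSV / JSON / YAML serialization for trials, anatomies and results.

Time series travel as CSV with a header row and one frame per row;
anatomy, models and fits as JSON; run configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic_data import AnatomyFixture, ContactForceRecord, GaitTrial

__all__ = [
    "write_anatomy", "read_anatomy", "write_trial", "read_trial",
    "write_record", "read_record", "write_points", "read_points",
    "write_trace", "load_config",
]

_TRIAL_COLUMNS = (
    ["time"]
    + [f"pelvis_{c}" for c in ("tx", "ty", "tz", "rx", "ry", "rz")]
    + ["hip_flexion", "hip_adduction", "hip_rotation", "knee_flexion",
       "ankle_flexion"]
    + [f"grf_{c}" for c in "xyz"] + [f"cop_{c}" for c in "xyz"]
)


def write_anatomy(anatomy: AnatomyFixture, path) -> None:
    Path(path).write_text(json.dumps(anatomy.to_dict(), indent=1))


def read_anatomy(path) -> AnatomyFixture:
    return AnatomyFixture.from_dict(json.loads(Path(path).read_text()))


def write_trial(trial: GaitTrial, path) -> None:
    data = np.column_stack([
        trial.time, trial.pelvis_pose, trial.hip_angles, trial.knee_flexion,
        trial.ankle_flexion, trial.grf, trial.cop])
    pd.DataFrame(data, columns=_TRIAL_COLUMNS).to_csv(path, index=False)


def read_trial(path) -> GaitTrial:
    df = pd.read_csv(path)
    return GaitTrial(
        time=df["time"].to_numpy(),
        pelvis_pose=df[_TRIAL_COLUMNS[1:7]].to_numpy(),
        hip_angles=df[["hip_flexion", "hip_adduction", "hip_rotation"]].to_numpy(),
        knee_flexion=df["knee_flexion"].to_numpy(),
        ankle_flexion=df["ankle_flexion"].to_numpy(),
        grf=df[["grf_x", "grf_y", "grf_z"]].to_numpy(),
        cop=df[["cop_x", "cop_y", "cop_z"]].to_numpy(),
        heel_strikes=(0, len(df) - 1),
    )


def write_record(record: ContactForceRecord, path) -> None:
    pd.DataFrame({"percent_cycle": np.arange(101),
                  "force_bw": record.values}).to_csv(path, index=False)


def read_record(path) -> ContactForceRecord:
    df = pd.read_csv(path)
    return ContactForceRecord(values=df["force_bw"].to_numpy())


def write_trace(trace, path) -> None:
    """Ligament elongation trace as (percent_cycle, length_mm, strain)."""
    pd.DataFrame({"percent_cycle": trace.percent_cycle,
                  "length_mm": trace.length,
                  "strain": trace.strain}).to_csv(path, index=False)


def write_points(points, path) -> None:
    pd.DataFrame(np.asarray(points, dtype=float),
                 columns=["x", "y", "z"]).to_csv(path, index=False)


def read_points(path) -> np.ndarray:
    return pd.read_csv(path)[["x", "y", "z"]].to_numpy()


def load_config(path) -> dict:
    """Run configuration from YAML (or JSON, by extension)."""
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
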