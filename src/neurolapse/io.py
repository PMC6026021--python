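"""Readers and writers for the pipeline's on-disk formats.

CSV schemas are fixed and validated on read (a mismatch raises with the
missing columns listed); image stacks are 16-bit grayscale multi-page TIFF.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .morphometry import OBS_COLUMNS
from .tracking import Trajectory, compute_velocity
from .synthetic_data import ImagingSchedule

__all__ = [
    "TRAJ_COLUMNS",
    "read_observations",
    "write_observations",
    "read_trajectories",
    "write_trajectories",
    "trajectories_to_dataframe",
    "read_stack",
    "write_stack",
    "write_json",
    "config_hash",
]

TRAJ_COLUMNS = [
    "cell_id",
    "frame",
    "label",
    "x",
    "y",
    "area_um2",
    "node_count",
    "neurite_um",
    "velocity_um_per_h",
]


def _check_schema(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing columns: {', '.join(missing)}")


def write_observations(df: pd.DataFrame, path: str | Path) -> None:
    _check_schema(df, OBS_COLUMNS, "observations")
    df.to_csv(path, index=False)


def read_observations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, OBS_COLUMNS, "observations")
    return df


def trajectories_to_dataframe(
    trajectories: list[Trajectory], schedule: ImagingSchedule
) -> pd.DataFrame:
    rows = []
    for t in trajectories:
        vel = compute_velocity(t, schedule)
        for i, o in enumerate(t.observations):
            rows.append(
                {
                    "cell_id": t.cell_id,
                    "frame": o.frame,
                    "label": o.label,
                    "x": o.centroid_px[0],
                    "y": o.centroid_px[1],
                    "area_um2": o.area_um2,
                    "node_count": o.node_count,
                    "neurite_um": o.neurite_length_um,
                    "velocity_um_per_h": float(vel[i - 1]) if i >= 1 else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=TRAJ_COLUMNS)


def write_trajectories(df: pd.DataFrame, path: str | Path) -> None:
    _check_schema(df, TRAJ_COLUMNS, "trajectories")
    df.to_csv(path, index=False)


def read_trajectories(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, TRAJ_COLUMNS, "trajectories")
    return df


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a (T, H, W) array as a 16-bit grayscale multi-page TIFF."""
    tifffile.imwrite(
        path, np.asarray(stack, dtype=np.uint16), photometric="minisblack"
    )


def read_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(np.uint16)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable config, for provenance."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
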