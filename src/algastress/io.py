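"""File I/O: TIFF stacks, schema-checked CSV tables, YAML configs.

All on-disk coordinates are in um.  Each table reader validates the header
and raises a :class:`SchemaError` naming the missing columns, so malformed
hand-edited files fail loudly at the boundary rather than deep in an
analysis.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

DETECTIONS_SCHEMA = ["frame", "x_um", "y_um"]
TRACKS_SCHEMA = ["track_id", "frame", "x_um", "y_um"]
STEPS_SCHEMA = ["track_id", "t", "vx", "vy", "speed"]
ANGLES_SCHEMA = ["track_id", "t", "dtheta", "dtheta_signed"]
GROWTH_SCHEMA = ["time_hr"]
PIGMENTS_SCHEMA = ["sample_id", "A663", "A645", "A750", "volume_ml"]


class SchemaError(ValueError):
    """A CSV is missing required columns."""


def _check_schema(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (frames, h, w) uint8/uint16 stack as multi-page TIFF."""
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF into a (frames, h, w) array."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None, ...]
    return arr


def _read_csv(path: str | Path, schema: list[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, schema, what)
    return df


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_detections(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, DETECTIONS_SCHEMA, "detections")


def read_tracks(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, TRACKS_SCHEMA, "tracks")


def read_steps(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, STEPS_SCHEMA, "steps")


def read_angles(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, ANGLES_SCHEMA, "angles")


def read_growth(path: str | Path) -> pd.DataFrame:
    """Growth table: time_hr plus one column per replicate."""
    df = _read_csv(path, GROWTH_SCHEMA, "growth")
    if df.shape[1] < 2:
        raise SchemaError("growth table needs at least one replicate column")
    return df


def read_pigment_samples(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, PIGMENTS_SCHEMA, "pigment samples")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def save_config(path: str | Path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
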