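"""File formats: float/label TIFF maps, CSV tables, JSON configs/reports.

Maps are 32-bit float TIFF with NaN encoding masked pixels; label masks
are 16-bit unsigned TIFF; tables are CSV via pandas; configuration and
reports are JSON.  Round-trips are lossless at the stored precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import RunConfig

__all__ = [
    "write_map",
    "read_map",
    "write_labels",
    "read_labels",
    "write_table",
    "read_table",
    "write_json",
    "read_json",
    "load_config",
    "save_config",
]


def write_map(path: str | Path, values: np.ndarray) -> None:
    """Write a float map as 32-bit float TIFF (NaN = masked)."""
    tifffile.imwrite(str(path), np.asarray(values, dtype=np.float32))


def read_map(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.dtype.kind != "f":
        raise ValueError(f"{path}: expected float TIFF, got dtype {arr.dtype}")
    return arr.astype(np.float64)


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    arr = np.asarray(labels)
    if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels out of uint16 range")
    tifffile.imwrite(str(path), arr.astype(np.uint16))


def read_labels(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.dtype.kind not in "ui":
        raise ValueError(f"{path}: expected integer label TIFF, got {arr.dtype}")
    return arr.astype(np.int32)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def save_config(path: str | Path, config: RunConfig) -> None:
    write_json(path, config.model_dump(mode="json"))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration (schema-checked)."""
    return RunConfig.model_validate(read_json(path))
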