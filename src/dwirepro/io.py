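"""File I/O: NIfTI volumes, measurement-table CSV, YAML/JSON config."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_table",
    "load_table",
    "load_config",
]

TABLE_COLUMNS = ["scanner", "volunteer", "session", "region", "metric", "value"]


def save_nifti(data: np.ndarray, path, voxel_size=(1.0, 1.0, 1.0),
               description: str = "") -> None:
    """Write an array as NIfTI-1; ``description`` lands in the header
    descrip field (used to record parameter-map units)."""
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def save_table(table: pd.DataFrame, path) -> None:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table missing columns {missing}")
    table[TABLE_COLUMNS].to_csv(path, index=False)


def load_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table missing columns {missing}")
    return table


def load_config(path) -> dict:
    """Read a YAML or JSON run configuration."""
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
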