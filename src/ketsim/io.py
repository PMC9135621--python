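"""NIfTI-1 and TSV I/O with grid validation and JSON sidecars.

Volumes are written through nibabel with their affine preserved (RAS+ by
convention); tables are tab-separated with typed columns.  Every pipeline
output may carry a JSON sidecar recording the stage, configuration hash and
seed, so any run directory is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import GridMismatchError, ValidationError


def write_map(path, data: np.ndarray, affine: Optional[np.ndarray] = None) -> Path:
    """Write a 3D/4D array as NIfTI-1 (float64 preserved bitwise)."""
    path = Path(path)
    affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))
    return path


def read_map(path):
    """Read a NIfTI-1 volume; returns ``(data, affine)`` with NaNs preserved."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine, dtype=float)


def write_table(path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")


def write_json(path, payload: Dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify) + "\n")
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)}")


def write_sidecar(output_path, stage: str, config_hash: str, seed: int, extra: Optional[Dict] = None) -> Path:
    payload = {"stage": stage, "config_hash": config_hash, "rng_seed": int(seed)}
    if extra:
        payload.update(extra)
    return write_json(Path(str(output_path) + ".json"), payload)


def validate_shared_grid(paths: Iterable) -> tuple:
    """Check a set of NIfTI files share one grid and affine; name offenders."""
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValidationError("no volumes to validate")
    ref_shape = None
    ref_affine = None
    offenders = []
    for p in paths:
        img = nib.load(str(p))
        shape = tuple(img.shape[:3])
        affine = np.asarray(img.affine)
        if ref_shape is None:
            ref_shape, ref_affine = shape, affine
        elif shape != ref_shape or not np.allclose(affine, ref_affine):
            offenders.append(str(p))
    if offenders:
        raise GridMismatchError(
            f"volumes do not share the reference grid {ref_shape}: " + "; ".join(offenders)
        )
    return ref_shape
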