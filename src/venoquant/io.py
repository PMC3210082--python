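"""NIfTI / CSV / JSON input-output.

Volumes travel as NIfTI-1 with the voxel spacing (mm) in the header zooms;
reading a volume without usable spacing is an error because ATVV and DFV
need physical units. Cohort tables and reports are plain CSV; provenance and
phantom truth are JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

log = logging.getLogger("venoquant")

__all__ = ["read_volume", "write_volume", "read_cohort_csv", "write_report", "write_json"]

REPORT_COLUMNS = [
    "subject", "condition", "atvv_total_ml",
    "atvv_class1_ml", "atvv_class2_ml", "atvv_class3_ml", "atvv_class4_ml",
    "vif", "mean_dfv_mm", "icv_ml",
]


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    """Load a NIfTI volume; returns (data, spacing mm, affine)."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid voxel spacing; physical units required")
    data = np.asanyarray(img.dataobj)
    return np.asarray(data), tuple(float(z) for z in zooms), img.affine


def write_volume(path, data: np.ndarray, spacing: tuple[float, float, float],
                 affine: np.ndarray | None = None) -> None:
    """Write a NIfTI volume with spacing recorded in the affine and zooms."""
    if affine is None:
        affine = np.diag(list(spacing) + [1.0])
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def read_cohort_csv(path, required: tuple[str, ...] = ("subject", "group")) -> pd.DataFrame:
    """Read a tidy cohort CSV; unknown columns are preserved with a warning."""
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    known = set(required) | {
        "condition", "atvv_total_ml", "mean_dfv_mm", "vif", "icv_ml", "vhiss",
        "ccsvi_positive",
    } | {f"vhiss{i}" for i in range(1, 6)} | {f"fulfilled{i}" for i in range(1, 6)} \
      | {f"atvv_class{k}_ml" for k in range(1, 5)}
    extra = [c for c in df.columns if c not in known]
    if extra:
        log.warning("unknown cohort column(s) preserved: %s", extra)
    return df


def write_report(path, rows: list[dict]) -> None:
    """Write per-subject VVV report rows as CSV."""
    df = pd.DataFrame(rows)
    ordered = [c for c in REPORT_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in REPORT_COLUMNS
    ]
    df[ordered].to_csv(path, index=False)


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
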