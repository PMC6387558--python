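"""NIfTI and TSV input/output.

Volumes are stored as float32 NIfTI-1 with a fixed diagonal affine
(voxel size in mm); statistics are always computed in float64.  Metadata
travels in UTF-8 tab-delimited tables with a header row.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import SubjectScan

__all__ = ["write_volume", "read_volume", "read_scan", "write_scans",
           "read_cohort", "write_table", "read_table"]


def write_volume(volume: np.ndarray, voxel_size_mm: float, path) -> Path:
    """Write a 3-D volume as float32 .nii / .nii.gz."""
    path = Path(path)
    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    nib.save(img, path)
    return path


def read_volume(path) -> tuple[np.ndarray, float]:
    """Read a 3-D NIfTI volume; returns (data, voxel size in mm)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: non-finite voxel values")
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise ValueError(f"{path}: anisotropic voxels {zooms} unsupported")
    return data, float(zooms[0])


def read_scan(path, *, age: float = 0.0,
              subject_id: str | None = None, cohort: str = "unknown",
              expected_shape=None) -> SubjectScan:
    """Read one uptake volume as a SubjectScan.

    Demographics normally come from the cohort metadata table; this
    low-level reader accepts them directly."""
    data, voxel = read_volume(path)
    if expected_shape is not None and data.shape != tuple(expected_shape):
        raise ValueError(
            f"{path}: grid {data.shape} does not match cohort grid "
            f"{tuple(expected_shape)}")
    sid = subject_id or Path(path).name.split(".")[0]
    return SubjectScan(volume=data, voxel_size_mm=voxel, age=age,
                       subject_id=sid, cohort=cohort)


def write_scans(scans, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in scans:
        write_volume(s.volume, s.voxel_size_mm, out_dir / f"{s.subject_id}.nii.gz")
    return out_dir


def read_cohort(scan_dir, meta_path):
    """Read scans listed in a metadata TSV; returns (controls, patients)."""
    meta = read_table(meta_path)
    scan_dir = Path(scan_dir)
    controls, patients = [], []
    for _, row in meta.iterrows():
        scan = read_scan(scan_dir / f"{row.subject_id}.nii.gz",
                         age=float(row.age), subject_id=row.subject_id,
                         cohort=row.cohort)
        if row.cohort == "control":
            controls.append(scan)
        else:
            pattern = row.pattern if isinstance(row.pattern, str) and row.pattern else None
            patients.append(dataclasses.replace(scan, pattern=pattern))
    return controls, patients, meta


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       na_values=[""])
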