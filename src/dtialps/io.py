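"""File formats: NIfTI-1 volumes, FSL bval/bvec sidecars, cohort CSV,
ROI-spec YAML/JSON and the JSON analysis report.

All writes are atomic (temp file in the target directory + rename), so a
crashed run never leaves a half-written file that parses as valid.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .alps import RoiSpec
from .gradients import GradientTable
from .tensor import DwiVolume, ScalarMaps

__all__ = [
    "read_dwi", "write_dwi", "read_gradient_table", "write_gradient_table",
    "write_scalar_maps", "read_cohort", "write_cohort", "read_roi_specs",
    "write_roi_specs", "write_json", "atomic_write_bytes",
]

logger = logging.getLogger(__name__)


def atomic_write_bytes(path: Path, payload: bytes) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_text(path: Path, text: str) -> None:
    atomic_write_bytes(path, text.encode("utf-8"))


# ---------------------------------------------------------------- gradients

def read_gradient_table(path_bval, path_bvec) -> GradientTable:
    """FSL dialect: bvals one whitespace-separated row; bvecs three rows
    holding the x, y, z components in the image frame.

    Slightly non-unit directions (norm off by more than 1e-3) trigger a
    warning and are renormalized; grossly malformed files raise.
    """
    bvals = np.loadtxt(path_bval, ndmin=1)
    if bvals.ndim != 1:
        raise ValueError(f"{path_bval}: expected a single row of b-values")
    bvecs = np.loadtxt(path_bvec, ndmin=2)
    if bvecs.shape[0] != 3:
        raise ValueError(f"{path_bvec}: expected 3 rows (x, y, z components)")
    if bvecs.shape[1] != bvals.shape[0]:
        raise ValueError(
            f"bval count ({bvals.shape[0]}) != bvec count ({bvecs.shape[1]})"
        )
    vecs = bvecs.T.copy()
    nz = bvals > 0
    norms = np.linalg.norm(vecs[nz], axis=1)
    if np.any(norms == 0):
        raise ValueError(f"{path_bvec}: zero direction on a nonzero-b entry")
    off = np.abs(norms - 1.0) > 1e-3
    if np.any(off):
        warnings.warn(
            f"{path_bvec}: {int(off.sum())} direction(s) deviate from unit "
            "norm by > 1e-3; renormalizing", stacklevel=2,
        )
    renorm = np.abs(norms - 1.0) > 1e-12  # leave exactly-unit vectors untouched
    if np.any(renorm):
        idx = np.flatnonzero(nz)[renorm]
        vecs[idx] /= norms[renorm][:, None]
    return GradientTable(bvals, vecs)


def write_gradient_table(gtab: GradientTable, path_bval, path_bvec) -> None:
    _atomic_text(Path(path_bval),
                 " ".join(f"{b:.6g}" for b in gtab.bvals) + "\n")
    rows = [" ".join(f"{v:.17g}" for v in gtab.bvecs[:, k]) for k in range(3)]
    _atomic_text(Path(path_bvec), "\n".join(rows) + "\n")


# ------------------------------------------------------------------- NIfTI

def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def _save_nifti(path: Path, data: np.ndarray, voxel_size) -> None:
    img = nib.Nifti1Image(np.asarray(data), _affine(voxel_size))
    img.header.set_zooms(tuple(voxel_size) + (1.0,) * (data.ndim - 3))
    atomic_write_bytes(Path(path), img.to_bytes())


def write_dwi(dwi: DwiVolume, path_nifti, path_bval, path_bvec) -> None:
    _save_nifti(Path(path_nifti), dwi.intensities, dwi.voxel_size)
    write_gradient_table(dwi.gradient_table, path_bval, path_bvec)


def read_dwi(path_nifti, path_bval, path_bvec) -> DwiVolume:
    img = nib.load(str(path_nifti))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path_nifti}: expected a 4D volume, got {data.ndim}D")
    gtab = read_gradient_table(path_bval, path_bvec)
    if data.shape[3] != len(gtab):
        raise ValueError(
            f"{path_nifti}: 4th axis ({data.shape[3]}) != gradient table "
            f"length ({len(gtab)})"
        )
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DwiVolume(data, voxel_size, gtab)


def write_scalar_maps(maps: ScalarMaps, out_dir) -> list[Path]:
    """Write FA, MD, color-FA and the axis diffusivities as NIfTI-1 files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, data in (
        ("fa", maps.fa), ("md", maps.md), ("color_fa", maps.color_fa),
        ("dxx", maps.dxx), ("dyy", maps.dyy), ("dzz", maps.dzz),
    ):
        path = out_dir / f"{name}.nii"
        _save_nifti(path, data, maps.voxel_size)
        written.append(path)
    return written


def read_scalar_maps(maps_dir) -> ScalarMaps:
    maps_dir = Path(maps_dir)
    arrays = {}
    voxel_size = None
    for name in ("fa", "md", "color_fa", "dxx", "dyy", "dzz"):
        img = nib.load(str(maps_dir / f"{name}.nii"))
        arrays[name] = np.asanyarray(img.dataobj, dtype=float)
        voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    valid = np.isfinite(arrays["fa"])
    return ScalarMaps(valid=valid, voxel_size=voxel_size, **arrays)


# ------------------------------------------------------------------ tables

def write_cohort(df: pd.DataFrame, path) -> None:
    _atomic_text(Path(path), df.to_csv(index=False))


def read_cohort(path) -> pd.DataFrame:
    from .cohort import COHORT_COLUMNS
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing cohort columns {missing}")
    return df


# ---------------------------------------------------------------- ROI spec

def read_roi_specs(path) -> list[RoiSpec]:
    """ROI list from YAML or JSON: entries with role, hemisphere, slice,
    center [x, y] and optional diameter_mm."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"{path}: expected a list of ROI entries")
    rois = []
    for entry in raw:
        rois.append(RoiSpec(
            role=entry["role"],
            hemisphere=entry["hemisphere"],
            slice_index=int(entry["slice"]),
            center=tuple(float(v) for v in entry["center"]),
            diameter_mm=float(entry.get("diameter_mm", 5.0)),
        ))
    return rois


def write_roi_specs(rois: list[RoiSpec], path) -> None:
    entries = [
        {"role": r.role, "hemisphere": r.hemisphere, "slice": r.slice_index,
         "center": [float(c) for c in r.center],
         "diameter_mm": r.diameter_mm}
        for r in rois
    ]
    _atomic_text(Path(path), yaml.safe_dump(entries, sort_keys=False))


def write_json(obj, path) -> None:
    _atomic_text(Path(path), json.dumps(obj, indent=2, sort_keys=False) + "\n")
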