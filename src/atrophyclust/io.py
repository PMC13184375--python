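"""NIfTI / CSV / YAML readers and writers.

Thin wrappers around :mod:`nibabel` and :mod:`pandas` so that every other
module works purely on in-memory containers.  Volumes are written as
NIfTI-1 with an isotropic diagonal affine derived from the voxel size.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .maps import SubjectMaps

__all__ = [
    "write_subject_maps",
    "read_subject_maps",
    "write_covariates",
    "read_covariates",
    "load_yaml",
    "dump_yaml",
    "write_stat_map",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def write_subject_maps(maps: SubjectMaps, out_dir: str | Path) -> list[Path]:
    """One NIfTI volume per subject plus the mask; returns written paths."""
    if maps.mask is None:
        raise ValueError("stacked maps cannot be written as volumes")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(maps.voxel_size_mm)
    paths = []
    for i, sid in enumerate(maps.subject_ids):
        vol = maps.to_volume(i)
        p = out / f"{sid}_{maps.channel}.nii"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), aff), p)
        paths.append(p)
    mask_path = out / f"mask_{maps.channel}.nii"
    nib.save(nib.Nifti1Image(maps.mask.astype(np.uint8), aff), mask_path)
    paths.append(mask_path)
    return paths


def read_subject_maps(
    nifti_dir: str | Path, channel: str, subject_ids: list[str],
    voxel_size_mm: float | None = None,
) -> SubjectMaps:
    """Load per-subject volumes written by :func:`write_subject_maps`."""
    d = Path(nifti_dir)
    mask_img = nib.load(d / f"mask_{channel}.nii")
    mask = np.asarray(mask_img.dataobj).astype(bool)
    if voxel_size_mm is None:
        voxel_size_mm = float(abs(mask_img.affine[0, 0]))
    rows = []
    for sid in subject_ids:
        img = nib.load(d / f"{sid}_{channel}.nii")
        rows.append(np.asarray(img.dataobj, dtype=float)[mask])
    return SubjectMaps(
        np.array(rows), mask, voxel_size_mm, channel, list(subject_ids)
    )


def write_covariates(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
    return path


def write_stat_map(
    stat, mask: np.ndarray, voxel_size_mm: float, out_prefix: str | Path
) -> dict[str, Path]:
    """Write a StatMap as t / -log10(p) / significance NIfTI volumes."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(voxel_size_mm)
    paths = {}

    def _vol(values: np.ndarray, dtype=np.float32) -> np.ndarray:
        vol = np.zeros(mask.shape, dtype=dtype)
        vol[mask] = values.astype(dtype)
        return vol

    for name, values in (
        ("t", stat.t),
        ("neglog10p", -np.log10(np.maximum(stat.p_uncorrected, 1e-300))),
    ):
        p = out_prefix.parent / f"{out_prefix.name}_{name}.nii"
        nib.save(nib.Nifti1Image(_vol(values), aff), p)
        paths[name] = p
    p = out_prefix.parent / f"{out_prefix.name}_sig.nii"
    nib.save(
        nib.Nifti1Image(_vol(stat.significant.astype(np.uint8), np.uint8), aff),
        p,
    )
    paths["sig"] = p
    meta = {
        "correction": stat.correction,
        "threshold": stat.threshold,
        "covariates_used": list(stat.covariates_used),
        "n_group": stat.n_group,
        "n_control": stat.n_control,
        "df": stat.df,
    }
    mp = out_prefix.parent / f"{out_prefix.name}_meta.json"
    mp.write_text(json.dumps(meta, indent=2))
    paths["meta"] = mp
    return paths
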