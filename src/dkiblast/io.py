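"""Readers and writers for the pipeline's on-disk formats.

DWI series travel as 4D NIfTI-1 plus FSL-style ``.bval``/``.bvec`` text
tables (space-separated; one row of b-values, three rows of vector
components). Parameter maps are 3D NIfTI on the input grid with a JSON
sidecar holding configuration and clamp statistics. Longitudinal tables
are tidy CSV with columns subject,group,time,region,measure,value. ROI
masks are integer-label NIfTI with a YAML label map. A layout-configurable
importer handles study spreadsheets (XLS/XLSX) deposited with per-animal
imaging values.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .dki import DWISeries, ParamMaps
from .roi import ROIMask

__all__ = [
    "read_dwi",
    "write_dwi",
    "write_param_maps",
    "read_param_maps",
    "write_cohort_csv",
    "read_cohort_csv",
    "load_roi_masks",
    "import_study_spreadsheet",
]

COHORT_COLUMNS = ["subject", "group", "time", "region", "measure", "value"]


def write_dwi(series: DWISeries, out_prefix) -> dict:
    """Write a series as NIfTI + .bval/.bvec; returns the paths written."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(series.data.astype(np.float64), series.affine)
    img.header.set_zooms(tuple(series.voxel_size) + (1.0,))
    nii_path = out_prefix.with_suffix(".nii")
    nib.save(img, nii_path)
    bvals = series.scheme.bvals
    bvecs = series.scheme.bvecs.T  # 3 rows, one per axis
    bval_path = out_prefix.with_suffix(".bval")
    bvec_path = out_prefix.with_suffix(".bvec")
    np.savetxt(bval_path, bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, bvecs, fmt="%.9f")
    paths = {"nifti": nii_path, "bval": bval_path, "bvec": bvec_path}
    if series.mask is not None:
        mask_path = out_prefix.parent / (out_prefix.name + "_mask.nii")
        nib.save(
            nib.Nifti1Image(series.mask.astype(np.uint8), series.affine), mask_path
        )
        paths["mask"] = mask_path
    return paths


def read_dwi(nifti_path, bval_path, bvec_path, mask_path=None) -> DWISeries:
    """Load a 4D NIfTI with its gradient tables into a DWISeries.

    Counts must agree between the tables and the fourth NIfTI dimension;
    non-zero gradient vectors must be unit within 1e-3 while zero vectors
    are accepted only on b = 0 rows. Volumes may arrive in any order — they
    are canonicalized against the shared direction set.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{nifti_path}: expected 4D data, got {data.ndim}D")
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvals.size != data.shape[3]:
        raise ValueError(
            f"bval count {bvals.size} != volume count {data.shape[3]}"
        )
    nonzero = bvals > 0
    zero_vec = np.linalg.norm(bvecs, axis=1) < 1e-8
    if np.any(nonzero & zero_vec):
        raise ValueError("zero gradient vector on a b > 0 volume")
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) != 0
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DWISeries.from_tables(
        data, bvals, bvecs, voxel_size, mask=mask, affine=img.affine
    )


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_param_maps(maps: ParamMaps, out_dir, config: dict | None = None) -> dict:
    """Write MD/FA/MK/flags NIfTI plus a JSON sidecar with fit statistics."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = maps.affine if maps.affine is not None else np.eye(4)
    paths = {}
    for name in ("MD", "FA", "MK"):
        p = out_dir / f"{name}.nii"
        nib.save(nib.Nifti1Image(getattr(maps, name).astype(np.float64), affine), p)
        paths[name] = p
    p = out_dir / "flags.nii"
    nib.save(nib.Nifti1Image(maps.flags.astype(np.int16), affine), p)
    paths["flags"] = p
    config = dict(config or {})
    sidecar = {
        "config": config,
        "config_hash": _config_hash(config),
        "n_clamped_kapp": int(maps.n_clamped_kapp),
        "flag_counts": {
            str(k): int(v)
            for k, v in zip(*np.unique(maps.flags, return_counts=True))
        },
    }
    sp = out_dir / "fit_log.json"
    sp.write_text(json.dumps(sidecar, indent=2, default=str))
    paths["sidecar"] = sp
    return paths


def read_param_maps(out_dir) -> ParamMaps:
    out_dir = Path(out_dir)
    imgs = {n: nib.load(str(out_dir / f"{n}.nii")) for n in ("MD", "FA", "MK")}
    flags = nib.load(str(out_dir / "flags.nii"))
    return ParamMaps(
        MD=np.asarray(imgs["MD"].dataobj, dtype=float),
        FA=np.asarray(imgs["FA"].dataobj, dtype=float),
        MK=np.asarray(imgs["MK"].dataobj, dtype=float),
        flags=np.asarray(flags.dataobj).astype(np.int16),
        affine=imgs["MD"].affine,
    )


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in table.columns] + [
        c for c in table.columns if c not in COHORT_COLUMNS
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table[cols].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")
    return df


def load_roi_masks(label_nifti_path, label_map) -> list:
    """Load ROI masks from an integer-label NIfTI and a label map.

    ``label_map`` is ``{label_int: {"region": ..., "side": ...}}`` or a path
    to a YAML file with that structure.
    """
    if not isinstance(label_map, dict):
        label_map = yaml.safe_load(Path(label_map).read_text())
    labels = np.asarray(nib.load(str(label_nifti_path)).dataobj).astype(int)
    masks = []
    for label, meta in sorted(label_map.items()):
        voxels = labels == int(label)
        masks.append(
            ROIMask(region=meta["region"], side=meta.get("side", "midline"), voxels=voxels)
        )
    return masks


def import_study_spreadsheet(
    path,
    column_map: dict | None = None,
    sheet=0,
    time_columns: list | None = None,
) -> pd.DataFrame:
    """Import a per-animal imaging spreadsheet into the longitudinal format.

    Two layouts are supported, since deposited supplementary files rarely
    document theirs:

    long
        One row per subject x time x region x measure; ``column_map`` maps
        the spreadsheet's column names onto
        subject/group/time/region/measure/value.
    wide
        One row per subject x region x measure with one column per time
        point; pass the spreadsheet's time columns in ``time_columns`` and
        map the identifier columns through ``column_map``.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    if time_columns:
        id_cols = [c for c in ("subject", "group", "region", "measure") if c in df.columns]
        df = df.melt(
            id_vars=id_cols,
            value_vars=time_columns,
            var_name="time",
            value_name="value",
        )
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"spreadsheet import missing columns {missing}; "
            "adjust column_map/time_columns for the deposited layout"
        )
    return df[COHORT_COLUMNS + [c for c in df.columns if c not in COHORT_COLUMNS]]
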