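"""Readers and writers for the pipeline's on-disk formats.

Regional series travel as TSV with a YAML sidecar carrying TR and
region ids; trial, motion, physiology and finding tables are plain
TSV; volumes and masks are NIfTI (nibabel) with a diagonal affine
built from the voxel size and world origin.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .preprocess import RegionalSeries
from .voxelmap import VolumeSeries

__all__ = [
    "write_regional_series",
    "read_regional_series",
    "write_volume",
    "read_volume",
    "write_findings",
    "sha256_of",
]


def write_regional_series(series: RegionalSeries, path) -> None:
    """TSV matrix (volumes x regions) plus a <stem>.yaml sidecar."""
    path = Path(path)
    df = pd.DataFrame(series.values, columns=[f"r{rid}" for rid in series.region_ids])
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    sidecar = {
        "tr_seconds": float(series.tr_seconds),
        "region_ids": [int(r) for r in series.region_ids],
        "subject_id": series.subject_id,
        "group": series.group,
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=True))


def read_regional_series(path) -> RegionalSeries:
    path = Path(path)
    values = pd.read_csv(path, sep="\t").to_numpy(dtype=float)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    return RegionalSeries(
        values=values,
        tr_seconds=meta["tr_seconds"],
        region_ids=np.asarray(meta["region_ids"]),
        subject_id=meta.get("subject_id", ""),
        group=meta.get("group", ""),
    )


def _affine(voxel_size_mm, origin_world_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(np.asarray(voxel_size_mm, dtype=float))
    aff[:3, 3] = np.asarray(origin_world_mm, dtype=float)
    return aff


def write_volume(vol: VolumeSeries, path) -> None:
    """4-D NIfTI with time as the last axis (scanner convention)."""
    data = np.moveaxis(vol.values, 0, -1)
    img = nib.Nifti1Image(data.astype(np.float32), _affine(vol.voxel_size_mm, vol.origin_world_mm))
    img.header.set_zooms((*vol.voxel_size_mm, vol.tr_seconds))
    nib.save(img, str(path))


def read_volume(path) -> VolumeSeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D NIfTI volume")
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError("only axis-aligned (diagonal) affines are supported")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return VolumeSeries(
        values=np.moveaxis(data, -1, 0),
        voxel_size_mm=np.abs(np.diag(aff[:3, :3])),
        origin_world_mm=aff[:3, 3],
        tr_seconds=tr,
    )


def write_findings(findings: list, path, region_names: dict | None = None) -> None:
    """Edge-finding table: i, j, optional names, direction, t, p, q."""
    rows = []
    for f in findings:
        row = dict(
            region_i=f.region_i,
            region_j=f.region_j,
            direction=f.direction,
            t=f.t_between,
            p=f.p_between,
            q=f.q_between,
        )
        if region_names:
            row["name_i"] = region_names.get(f.region_i, "")
            row["name_j"] = region_names.get(f.region_j, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
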