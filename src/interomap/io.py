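"""NIfTI / TSV / JSON readers and writers for pipeline artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from interomap.cohort import RoiSet, SubjectTimeSeries, VoxelGrid
from interomap.mapping import BinaryMask, ConnectivityMatrix, StatMap


def save_subject_nifti(ts: SubjectTimeSeries, grid: VoxelGrid, path) -> None:
    """Write one subject's series as a 4D NIfTI volume."""
    vol = ts.data.reshape(*grid.dims, ts.n_frames).astype(np.float32)
    img = nib.Nifti1Image(vol, grid.affine)
    img.header.set_zooms((grid.voxel_size_mm,) * 3 + (ts.tr_s,))
    nib.save(img, str(path))


def load_subject_nifti(path, tr_s: float | None = None,
                       run_boundaries: tuple[int, ...] = (0,)) -> tuple[SubjectTimeSeries, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()
    grid = VoxelGrid(dims=data.shape[:3], voxel_size_mm=float(zooms[0]))
    tr = tr_s if tr_s is not None else float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    ts = SubjectTimeSeries(
        subject_id=Path(path).stem.split(".")[0],
        data=data.reshape(-1, data.shape[3]),
        tr_s=tr,
        run_boundaries=run_boundaries,
    )
    return ts, grid


def save_volume_nifti(values: np.ndarray, grid: VoxelGrid, path) -> None:
    """Write a per-voxel 3D map (flat or shaped) as NIfTI."""
    vol = np.asarray(values).reshape(grid.dims).astype(np.float32)
    nib.save(nib.Nifti1Image(vol, grid.affine), str(path))


def save_statmap_nifti(stat_map: StatMap, stem: Path) -> list[Path]:
    paths = []
    for name, values in (("t", stat_map.t), ("p", stat_map.p), ("zmean", stat_map.z_mean)):
        path = Path(f"{stem}_{name}.nii.gz")
        save_volume_nifti(values, stat_map.grid, path)
        paths.append(path)
    return paths


def save_rois_nifti(rois: RoiSet, path) -> None:
    nib.save(nib.Nifti1Image(rois.to_label_volume().astype(np.int16), rois.grid.affine), str(path))


def load_rois_nifti(path, labels: list[str], category: dict[str, str]) -> tuple[VoxelGrid, RoiSet]:
    """Read an integer-labelled ROI volume (value i+1 = i-th label)."""
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj).astype(int).reshape(-1)
    grid = VoxelGrid(dims=img.shape[:3], voxel_size_mm=float(img.header.get_zooms()[0]))
    members = {}
    for i, label in enumerate(labels):
        members[label] = np.flatnonzero(vol == i + 1)
    return grid, RoiSet(grid=grid, members=members, category=category)


def load_parcellation_nifti(path) -> tuple[VoxelGrid, np.ndarray]:
    """Read an integer-labelled parcellation volume (0 = background) as a
    flat parcel-id array for Dice correspondence testing."""
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj).astype(int)
    grid = VoxelGrid(dims=vol.shape[:3], voxel_size_mm=float(img.header.get_zooms()[0]))
    return grid, vol.reshape(-1)


def save_confounds_tsv(confounds: pd.DataFrame, path) -> None:
    confounds.to_csv(path, sep="\t", index=False, float_format="%.6f")


def load_confounds_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_matrix_tsv(matrix: ConnectivityMatrix, stem: Path) -> list[Path]:
    paths = []
    for name, values in (("t", matrix.t), ("p", matrix.p),
                         ("significant", matrix.significant.astype(int))):
        path = Path(f"{stem}_{name}.tsv")
        pd.DataFrame(values, index=matrix.labels, columns=matrix.labels).to_csv(path, sep="\t")
        paths.append(path)
    return paths


def save_mask_nifti(mask: BinaryMask, path) -> None:
    save_volume_nifti(mask.data.astype(np.int16), mask.grid, path)


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
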