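"""NIfTI and table output helpers."""
from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import LesionCohort
from .grid import VoxelGrid
from .tracts import TractAtlas

__all__ = ["save_volume", "write_cohort", "write_atlas", "write_table"]


def save_volume(data: np.ndarray, grid: VoxelGrid, path: str | Path, dtype=None) -> Path:
    """Write a volume on the analysis grid as NIfTI-1."""
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, grid.affine())
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def write_cohort(cohort: LesionCohort, out_dir: str | Path) -> pd.DataFrame:
    """Write per-patient lesion maps and return the manifest table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, pid in enumerate(cohort.patient_ids):
        wml_path = out_dir / f"{pid}_wml.nii.gz"
        ll_path = out_dir / f"{pid}_ll.nii.gz"
        save_volume(cohort.maps["wml"][i], cohort.grid, wml_path, dtype=np.uint8)
        save_volume(cohort.maps["ll"][i], cohort.grid, ll_path, dtype=np.uint8)
        rows.append({"patient_id": pid, "wml_path": str(wml_path), "ll_path": str(ll_path)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest


def write_atlas(atlas: TractAtlas, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, vol in atlas.probabilities.items():
        paths[name] = save_volume(vol, atlas.grid, out_dir / f"tract_{name}.nii.gz",
                                  dtype=np.float32)
    return paths


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path
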