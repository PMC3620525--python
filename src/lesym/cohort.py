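"""Cohorts of co-registered binary lesion maps.

A cohort holds, for every patient, one binary white-matter-lesion (WML) map
and one binary lacunar-lesion (LL) map on a single shared voxel grid, plus
the derived total lesion volumes in template space ("normalised volumes").
Downstream voxel-wise statistics are computed on the stacked binary maps,
so loading validates strictly: values must be exactly 0/1 and all volumes
must agree on grid shape and affine.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import GridMismatchError, VoxelGrid

__all__ = [
    "LESION_CLASSES",
    "LesionCohort",
    "PrevalenceMap",
    "AnalysisMask",
    "read_cohort",
    "prevalence_map",
    "analysis_mask",
]

#: Recognised lesion classes: confluent white matter lesions and lacunes.
LESION_CLASSES = ("wml", "ll")

#: Tolerance (mm) within which input affines must agree across a cohort.
AFFINE_ATOL_MM = 1e-4


@dataclass
class LesionCohort:
    """Per-patient binary WML and LL maps on one shared grid.

    ``maps[cls]`` is a ``uint8`` array of shape ``(n_patients, *grid.shape)``
    with values in {0, 1}.  Total volumes are exact:
    lesioned-voxel count x voxel volume (mm^3) / 1000.
    """

    grid: VoxelGrid
    patient_ids: tuple[str, ...]
    maps: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        ids = tuple(str(p) for p in self.patient_ids)
        if len(set(ids)) != len(ids):
            dupes = sorted({p for p in ids if ids.count(p) > 1})
            raise ValueError(f"duplicate patient ids: {dupes}")
        self.patient_ids = ids
        for cls in LESION_CLASSES:
            if cls not in self.maps:
                raise ValueError(f"missing lesion class {cls!r}")
            arr = np.asarray(self.maps[cls])
            if arr.shape != (len(ids), *self.grid.shape):
                raise ValueError(
                    f"{cls} maps have shape {arr.shape}, expected "
                    f"{(len(ids), *self.grid.shape)}"
                )
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{cls} maps must be strictly binary (0/1)")
            self.maps[cls] = arr.astype(np.uint8, copy=False)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def lesion_matrix(self, lesion_class: str, mask: np.ndarray | None = None) -> np.ndarray:
        """Boolean (n_patients, n_voxels) matrix, optionally restricted to a mask."""
        _check_class(lesion_class)
        flat = self.maps[lesion_class].reshape(self.n_patients, -1).astype(bool)
        if mask is not None:
            flat = flat[:, np.asarray(mask, dtype=bool).ravel()]
        return flat

    def total_volumes(self) -> pd.DataFrame:
        """Total normalised lesion volume (ml) per patient and class."""
        vol = self.grid.voxel_volume_mm3
        data = {
            f"{cls}_total_ml": self.maps[cls].reshape(self.n_patients, -1).sum(axis=1)
            * vol
            / 1000.0
            for cls in LESION_CLASSES
        }
        out = pd.DataFrame(data, index=pd.Index(self.patient_ids, name="patient_id"))
        out["ll_present"] = (out["ll_total_ml"] > 0).astype(int)
        return out


@dataclass
class PrevalenceMap:
    """Per-voxel count of patients lesioned at that voxel, for one class."""

    counts: np.ndarray
    lesion_class: str
    grid: VoxelGrid
    n_patients: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > self.n_patients:
            raise ValueError("prevalence counts must lie in [0, n_patients]")


@dataclass
class AnalysisMask:
    """Voxels eligible for voxel-wise testing (prevalence >= min_patients)."""

    mask: np.ndarray
    min_patients: int
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _check_class(lesion_class: str) -> None:
    if lesion_class not in LESION_CLASSES:
        raise ValueError(f"unknown lesion class {lesion_class!r}; expected one of {LESION_CLASSES}")


def read_cohort(manifest: str | Path | pd.DataFrame) -> LesionCohort:
    """Load a cohort from a manifest of per-patient NIfTI paths.

    The manifest is a tab-separated table (or DataFrame) with columns
    ``patient_id``, ``wml_path``, ``ll_path``.  All volumes must share one
    grid; affines must agree to within ``AFFINE_ATOL_MM``; values other
    than {0, 1} are rejected naming the offending file.
    """
    if isinstance(manifest, (str, Path)):
        table = pd.read_csv(manifest, sep="\t", dtype=str)
    else:
        table = manifest.copy()
    required = {"patient_id", "wml_path", "ll_path"}
    if not required.issubset(table.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")

    ids: list[str] = []
    stacks: dict[str, list[np.ndarray]] = {cls: [] for cls in LESION_CLASSES}
    ref_affine: np.ndarray | None = None
    ref_shape: tuple[int, ...] | None = None

    for row in table.itertuples(index=False):
        pid = str(row.patient_id)
        ids.append(pid)
        for cls, path in (("wml", row.wml_path), ("ll", row.ll_path)):
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj)
            if data.ndim != 3:
                raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
            if ref_shape is None:
                ref_shape = data.shape
                ref_affine = img.affine
            else:
                if data.shape != ref_shape:
                    raise GridMismatchError(
                        f"patient {pid}: {path} has shape {data.shape}, cohort grid is {ref_shape}"
                    )
                if not np.allclose(img.affine, ref_affine, atol=AFFINE_ATOL_MM):
                    raise GridMismatchError(
                        f"patient {pid}: {path} affine differs from the cohort affine "
                        f"by more than {AFFINE_ATOL_MM} mm"
                    )
            if not np.isin(data, (0, 1)).all():
                bad = np.unique(data[~np.isin(data, (0, 1))])[:5]
                raise ValueError(f"{path}: non-binary values {bad.tolist()}")
            stacks[cls].append(data.astype(np.uint8))

    if not ids:
        raise ValueError("empty manifest")
    voxel_sizes = tuple(float(v) for v in nib.affines.voxel_sizes(ref_affine))
    grid = VoxelGrid(shape=tuple(ref_shape), voxel_size_mm=voxel_sizes)
    maps = {cls: np.stack(stacks[cls]) for cls in LESION_CLASSES}
    return LesionCohort(grid=grid, patient_ids=tuple(ids), maps=maps)


def prevalence_map(cohort: LesionCohort, lesion_class: str) -> PrevalenceMap:
    """Voxel-wise count of patients with a lesion of the given class."""
    _check_class(lesion_class)
    counts = cohort.maps[lesion_class].sum(axis=0, dtype=np.int32)
    return PrevalenceMap(
        counts=counts,
        lesion_class=lesion_class,
        grid=cohort.grid,
        n_patients=cohort.n_patients,
    )


def analysis_mask(prev: PrevalenceMap, min_patients: int = 5) -> AnalysisMask:
    """Eligibility mask: voxels affected in at least ``min_patients`` patients.

    Voxels affected in fewer patients are not considered for voxel-wise
    analysis; a voxel with exactly ``min_patients`` is included.
    """
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    return AnalysisMask(mask=prev.counts >= min_patients, min_patients=int(min_patients), grid=prev.grid)
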