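"""Tract-ROI analysis: atlas thresholding, tract selection, regional volumes.

A probabilistic white-matter-tract atlas (one probability volume per tract,
on the cohort grid) is binarised at a threshold (default 0.1).  Tracts are
then selected by overlap with the voxel-wise significance map — a tract is
selected when it contains more than ``min_total`` significant voxels, or a
single significant cluster overlapping it in more than ``min_cluster``
voxels (strict inequalities).  Finally, per-patient lesion volumes are
computed within each thresholded tract mask.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import LESION_CLASSES, LesionCohort
from .grid import GridMismatchError, VoxelGrid

__all__ = [
    "TractAtlas",
    "TractSummary",
    "binarize_atlas",
    "tract_summary",
    "regional_volumes",
    "regional_column",
]


@dataclass
class TractAtlas:
    """Named probability volumes on the shared grid.

    Probabilities must lie in [0, 1].  Atlases distributed on a percent
    scale (values up to 100) are auto-detected and rescaled with a warning.
    """

    grid: VoxelGrid
    probabilities: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, vol in self.probabilities.items():
            vol = np.asarray(vol, dtype=np.float64)
            if vol.shape != self.grid.shape:
                raise GridMismatchError(
                    f"tract {name!r}: volume shape {vol.shape} != grid {self.grid.shape}"
                )
            if vol.min() < 0:
                raise ValueError(f"tract {name!r}: negative probabilities")
            if vol.max() > 1.0:
                if vol.max() <= 100.0:
                    warnings.warn(
                        f"tract {name!r}: values exceed 1, interpreting as percent and dividing by 100",
                        stacklevel=2,
                    )
                    vol = vol / 100.0
                else:
                    raise ValueError(f"tract {name!r}: probabilities exceed 100")
            self.probabilities[name] = vol

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.probabilities)

    @classmethod
    def from_niftis(cls, paths: dict[str, str | Path]) -> "TractAtlas":
        """Load one probability NIfTI per tract (``{name: path}``)."""
        probs: dict[str, np.ndarray] = {}
        grid: VoxelGrid | None = None
        for name, path in paths.items():
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj).astype(np.float64)
            sizes = tuple(float(v) for v in nib.affines.voxel_sizes(img.affine))
            g = VoxelGrid(shape=data.shape, voxel_size_mm=sizes)
            if grid is None:
                grid = g
            elif not grid.matches(g):
                raise GridMismatchError(f"tract {name!r} is on a different grid")
            probs[name] = data
        if grid is None:
            raise ValueError("atlas needs at least one tract")
        return cls(grid=grid, probabilities=probs)


def binarize_atlas(atlas: TractAtlas, threshold: float = 0.1) -> dict[str, np.ndarray]:
    """Binary tract masks: probability >= threshold (inclusive boundary).

    The threshold must lie strictly inside (0, 1).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"atlas threshold must be in (0, 1), got {threshold}")
    return {name: vol >= threshold for name, vol in atlas.probabilities.items()}


@dataclass
class TractSummary:
    """Per-tract overlap with the significance map and the selection flag."""

    table: pd.DataFrame
    min_total: int
    min_cluster: int

    @property
    def selected(self) -> tuple[str, ...]:
        return tuple(self.table.index[self.table["selected"]])


def tract_summary(
    sig_mask: np.ndarray,
    cluster_labels: np.ndarray,
    masks: dict[str, np.ndarray],
    min_total: int = 50,
    min_cluster: int = 5,
    within_tract: bool = False,
    connectivity: int = 26,
) -> TractSummary:
    """Apply the tract-selection rule to a significance map.

    selected  <=>  (significant voxels in tract > min_total)
               or  (largest single-cluster overlap with tract > min_cluster)

    By default clusters are those of the *global* significance map,
    intersected with each tract mask; with ``within_tract=True`` clusters
    are recomputed inside each tract mask instead.
    """
    from .vlsm import label_clusters  # local import to avoid a cycle

    sig = np.asarray(sig_mask, dtype=bool)
    labels = np.asarray(cluster_labels)
    if labels.shape != sig.shape:
        raise GridMismatchError("cluster labels and significance mask differ in shape")
    rows = []
    for name, tract in masks.items():
        tract = np.asarray(tract, dtype=bool)
        if tract.shape != sig.shape:
            raise GridMismatchError(f"tract {name!r} mask shape differs from significance map")
        inside = sig & tract
        n_sig = int(inside.sum())
        if within_tract:
            local = label_clusters(inside, connectivity=connectivity)
            sizes = local.sizes
            largest = int(max(sizes.values())) if sizes else 0
        else:
            lab_in = labels[inside]
            largest = int(np.bincount(lab_in).max()) if lab_in.size else 0
        rows.append(
            {
                "tract": name,
                "n_significant": n_sig,
                "largest_cluster_overlap": largest,
                "selected": (n_sig > min_total) or (largest > min_cluster),
            }
        )
    table = pd.DataFrame(rows).set_index("tract")
    return TractSummary(table=table, min_total=int(min_total), min_cluster=int(min_cluster))


def regional_column(lesion_class: str, tract: str) -> str:
    """Column name used for a regional volume in tables and the ladder."""
    return f"{lesion_class}_{tract}_ml"


def regional_volumes(cohort: LesionCohort, masks: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-patient lesion volume (ml) within each tract mask, per class.

    volume = (lesion map AND tract mask) voxel count x voxel volume / 1000.
    Overlapping tract masks are allowed; each tract is counted independently.
    """
    vol_mm3 = cohort.grid.voxel_volume_mm3
    data: dict[str, np.ndarray] = {}
    for name, tract in masks.items():
        tract = np.asarray(tract, dtype=bool)
        if tract.shape != cohort.grid.shape:
            raise GridMismatchError(f"tract {name!r} mask is not on the cohort grid")
        flat = tract.ravel()
        for cls in LESION_CLASSES:
            lm = cohort.lesion_matrix(cls)
            data[regional_column(cls, name)] = lm[:, flat].sum(axis=1) * vol_mm3 / 1000.0
    return pd.DataFrame(data, index=pd.Index(cohort.patient_ids, name="patient_id"))
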