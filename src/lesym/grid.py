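"""Shared voxel-grid geometry for all volumes in an analysis.

Every lesion map, atlas volume and statistical map in a run lives on one
common grid (the maps are consumed already co-registered to a template);
this module holds that geometry and the compatibility checks that guard
against silent mixing of grids.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VoxelGrid", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of the common analysis grid.

    Parameters
    ----------
    shape : tuple of 3 int
        Number of voxels along each axis.
    voxel_size_mm : tuple of 3 float
        Voxel edge lengths in millimetres.
    space : str
        Free-text tag naming the reference space (e.g. a template name).
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    space: str = "common"

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        sizes = tuple(float(v) for v in self.voxel_size_mm)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape!r}")
        if len(sizes) != 3 or any(v <= 0 for v in sizes):
            raise ValueError(f"voxel sizes must be 3 positive reals, got {self.voxel_size_mm!r}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size_mm", sizes)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def voxel_volume_ml(self) -> float:
        # 1 ml == 1000 mm^3
        return self.voxel_volume_mm3 / 1000.0

    def affine(self) -> np.ndarray:
        """NIfTI affine for a grid with this spacing and origin at zero."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        return aff

    def matches(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size_mm, other.voxel_size_mm, atol=atol
        )

    def require_match(self, other: "VoxelGrid", context: str = "volumes") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"{context}: grid {other.shape}@{other.voxel_size_mm} does not match "
                f"analysis grid {self.shape}@{self.voxel_size_mm}"
            )
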