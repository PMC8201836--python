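"""Shared voxel-grid containers.

All masks and dose distributions in this package live on a single
:class:`VoxelGrid`: an isotropic, axis-aligned lattice expressed in the DICOM
patient coordinate system (x grows right->left, y anterior->posterior,
z inferior->superior).  Arrays are indexed ``[ix, iy, iz]`` and the world
position of a voxel *center* is ``origin_mm + index * spacing_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "VoxelGrid",
    "StructureMask",
    "StructureSet",
    "DoseGrid",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Isotropic 3D lattice shared by all structures and dose of one plan.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z).  Each entry must be >= 1.
    spacing_mm
        Isotropic voxel edge length in millimetres (> 0).
    origin_mm
        World coordinate (mm, DICOM patient axes) of the center of voxel
        ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing_mm: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be three entries >= 1, got {self.shape}")
        if not self.spacing_mm > 0:
            raise ValueError(f"spacing_mm must be > 0, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.spacing_mm) ** 3

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis."""
        return tuple(
            self.origin_mm[k] + self.spacing_mm * np.arange(self.shape[k])
            for k in range(3)
        )

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (nx,1,1)/(1,ny,1)/(1,1,nz) world-coordinate arrays."""
        ax, ay, az = self.axes_mm()
        return ax[:, None, None], ay[None, :, None], az[None, None, :]

    def affine(self) -> np.ndarray:
        """NIfTI-style 4x4 affine mapping voxel indices to mm coordinates."""
        aff = np.diag([self.spacing_mm] * 3 + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff


@dataclass
class StructureMask:
    """Named binary occupancy volume on a :class:`VoxelGrid`."""

    name: str
    grid: VoxelGrid
    data: np.ndarray  # bool, shape == grid.shape

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"mask '{self.name}' shape {self.data.shape} does not match "
                f"grid shape {self.grid.shape}"
            )
        if self.data.dtype != bool:
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(
                    f"mask '{self.name}' is not binary (values {vals[:8]}...)"
                )
            self.data = self.data.astype(bool)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_cm3

    def is_empty(self) -> bool:
        return not self.data.any()

    def centroid_mm(self) -> np.ndarray:
        """World coordinate of the occupied-voxel centroid."""
        if self.is_empty():
            raise ValueError(f"mask '{self.name}' is empty; centroid undefined")
        idx = np.argwhere(self.data)
        return np.asarray(self.grid.origin_mm) + self.grid.spacing_mm * idx.mean(axis=0)

    def with_name(self, name: str) -> "StructureMask":
        return StructureMask(name, self.grid, self.data.copy())


@dataclass
class StructureSet:
    """Collection of structure masks sharing one grid."""

    grid: VoxelGrid
    masks: dict[str, StructureMask] = field(default_factory=dict)

    def add(self, mask: StructureMask) -> None:
        if mask.grid != self.grid:
            raise ValueError(f"mask '{mask.name}' is on a different grid")
        self.masks[mask.name] = mask

    def __getitem__(self, name: str) -> StructureMask:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __iter__(self) -> Iterator[StructureMask]:
        return iter(self.masks.values())

    @property
    def names(self) -> list[str]:
        return list(self.masks.keys())

    def require(self, names: list[str]) -> None:
        missing = [n for n in names if n not in self.masks]
        if missing:
            raise KeyError(f"structure set is missing structures: {missing}")

    def volumes_cm3(self) -> Mapping[str, float]:
        return {name: m.volume_cm3 for name, m in self.masks.items()}


@dataclass
class DoseGrid:
    """Per-voxel physical dose in Gy (total over the boost course)."""

    grid: VoxelGrid
    data: np.ndarray  # float, Gy

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"dose shape {self.data.shape} does not match grid {self.grid.shape}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("dose grid contains non-finite values")
        if (self.data < 0).any():
            raise ValueError("dose grid contains negative values")

    def scaled(self, factor: float) -> "DoseGrid":
        """Return a globally scaled copy (factor >= 0)."""
        if factor < 0:
            raise ValueError("dose scale factor must be >= 0")
        return DoseGrid(self.grid, self.data * float(factor))

    @property
    def max_gy(self) -> float:
        return float(self.data.max())

    def values_in(self, mask: StructureMask) -> np.ndarray:
        if mask.grid != self.grid:
            raise ValueError("dose and mask are on different grids")
        return self.data[mask.data]
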