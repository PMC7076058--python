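"""Regular voxel grids in RAS world coordinates.

One convention is used throughout the package: 0-based voxel indices,
right-anterior-superior (RAS) world axes (x -> right, y -> anterior,
z -> superior), millimetre units, and the voxel-*center* convention —
the world coordinate of voxel (i, j, k) is ``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VoxelGrid"]


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a regular 3-D voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z); each entry >= 1.
    spacing
        Voxel edge length in mm per axis; each entry > 0.
    origin
        World coordinate (mm, RAS) of the *center* of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("shape, spacing and origin must each have 3 entries")
        if any(n < 1 for n in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    # -- coordinate transforms -------------------------------------------
    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel indices ``ijk`` (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return self.origin + ijk * np.asarray(self.spacing)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world points ``xyz`` (..., 3)."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1-D arrays of voxel-center world coordinates (mm)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (RAS, mm)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @classmethod
    def from_extent(
        cls,
        lo: tuple[float, float, float],
        hi: tuple[float, float, float],
        spacing: float | tuple[float, float, float],
    ) -> "VoxelGrid":
        """Grid whose voxel centers span ``[lo, hi]`` inclusively per axis."""
        if np.isscalar(spacing):
            spacing = (float(spacing),) * 3
        shape = tuple(
            int(round((hi[a] - lo[a]) / spacing[a])) + 1 for a in range(3)
        )
        return cls(shape=shape, spacing=tuple(spacing), origin=tuple(lo))

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )
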