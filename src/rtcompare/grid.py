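"""Regular 3-D voxel lattice shared by structure masks and dose grids.

Axis convention used throughout the package (LPS-like):

* x runs patient-right -> patient-left,
* y runs anterior -> posterior,
* z runs caudal -> cranial.

All world coordinates are millimetres.  The voxel centre of index
``(i, j, k)`` sits at ``origin + index * spacing``; indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VoxelGrid"]


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a regular axis-aligned 3-D lattice.

    Parameters
    ----------
    dims
        Number of voxels along (x, y, z); each >= 1.
    spacing
        Voxel spacing in mm along (x, y, z); each > 0.
    origin
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(dims) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("dims, spacing and origin must be length-3")
        if any(d < 1 for d in dims):
            raise ValueError(f"all dims must be >= 1, got {dims}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0, got {spacing}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    # ------------------------------------------------------------------
    def index_to_world(self, index) -> np.ndarray:
        """World coordinates (mm) of voxel centres for (..., 3) indices."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def world_to_index(self, world) -> np.ndarray:
        """Fractional voxel indices for (..., 3) world coordinates (mm)."""
        world = np.asarray(world, dtype=float)
        return (world - np.asarray(self.origin)) / np.asarray(self.spacing)

    def coordinate_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-D arrays of voxel-centre world coordinates along x, y, z."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.dims[a])
            for a in range(3)
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) voxel-centre world coordinates per axis."""
        lo = np.asarray(self.origin)
        hi = lo + (np.asarray(self.dims) - 1) * np.asarray(self.spacing)
        return lo, hi

    def matches(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        """True when the two lattices describe the same geometry."""
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )
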