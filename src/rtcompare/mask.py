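"""Binary structure masks and the volumetric operations on them.

A :class:`StructureMask` is one observer's voxelised delineation of a named
structure (target or organ at risk).  Operations here cover contour
rasterization, volume measurement, CTV-to-PTV margin expansion, structure
grouping, and the cranial/caudal/medial/lateral border measurements used to
compare observers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as _MplPath
from scipy import ndimage

from .grid import VoxelGrid

__all__ = [
    "EmptyMaskError",
    "StructureMask",
    "StructureSet",
    "BorderExtents",
    "rasterize_polygons",
    "volume_cc",
    "expand_mask",
    "union",
    "intersection",
    "subtract",
    "border_extents",
    "border_difference_table",
    "resample_mask",
]

logger = logging.getLogger(__name__)


class EmptyMaskError(ValueError):
    """Raised when an operation requires at least one occupied voxel."""


@dataclass
class StructureMask:
    """Boolean occupancy of one named structure over a voxel grid."""

    label: str
    grid: VoxelGrid
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.shape != self.grid.dims:
            raise ValueError(
                f"occupancy shape {occ.shape} does not match grid dims {self.grid.dims}"
            )
        self.occupancy = occ.astype(bool, copy=False)

    # ------------------------------------------------------------------
    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.occupancy))

    @property
    def is_empty(self) -> bool:
        return not self.occupancy.any()

    def volume_cc(self) -> float:
        return self.n_occupied * self.grid.voxel_volume_cc

    def occupied_centers(self) -> np.ndarray:
        """(N, 3) world coordinates (mm) of occupied voxel centres."""
        idx = np.argwhere(self.occupancy)
        return self.grid.index_to_world(idx)

    def copy(self, label: str | None = None) -> "StructureMask":
        return StructureMask(label or self.label, self.grid, self.occupancy.copy())


class StructureSet:
    """One observer's labelled collection of masks on a single grid."""

    def __init__(self, observer_id: str, masks: dict[str, StructureMask] | None = None):
        self.observer_id = observer_id
        self.masks: dict[str, StructureMask] = {}
        for m in (masks or {}).values():
            self.add(m)

    def add(self, mask: StructureMask) -> None:
        if mask.label in self.masks:
            raise ValueError(f"duplicate structure label {mask.label!r}")
        if self.masks:
            ref = next(iter(self.masks.values())).grid
            if not mask.grid.matches(ref):
                raise ValueError(
                    f"mask {mask.label!r} is not on the set's shared grid"
                )
        self.masks[mask.label] = mask

    @property
    def grid(self) -> VoxelGrid:
        if not self.masks:
            raise ValueError("empty structure set has no grid")
        return next(iter(self.masks.values())).grid

    def __contains__(self, label: str) -> bool:
        return label in self.masks

    def __getitem__(self, label: str) -> StructureMask:
        return self.masks[label]

    def labels(self) -> list[str]:
        return list(self.masks)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"StructureSet({self.observer_id!r}, {sorted(self.masks)})"


@dataclass(frozen=True)
class BorderExtents:
    """Extreme world coordinates of a structure, in mm.

    ``cranial_mm``/``caudal_mm`` are the maximum/minimum z of occupied voxel
    centres; ``medial_mm``/``lateral_mm`` are the x extremes resolved by the
    structure's laterality (for a left-sided structure the lateral border is
    the maximum x, the medial border the minimum x; mirrored on the right).
    """

    cranial_mm: float
    caudal_mm: float
    medial_mm: float
    lateral_mm: float
    laterality: str = "left"

    def __post_init__(self) -> None:
        if self.cranial_mm < self.caudal_mm:
            raise ValueError("cranial border must not lie below the caudal border")

    def as_dict(self) -> dict[str, float]:
        return {
            "cranial": self.cranial_mm,
            "caudal": self.caudal_mm,
            "medial": self.medial_mm,
            "lateral": self.lateral_mm,
        }


# ----------------------------------------------------------------------
# rasterization
# ----------------------------------------------------------------------

def rasterize_polygons(contours, grid: VoxelGrid, label: str = "structure") -> StructureMask:
    """Rasterize slice-wise closed planar contours into a binary mask.

    Parameters
    ----------
    contours
        Sequence of (N, 3) arrays of world coordinates in mm.  Each contour
        must be a closed, non-self-intersecting polygon lying on a constant-z
        plane that coincides with a grid slice (within half a slice spacing).
        The closing edge from the last to the first vertex is implicit.
    grid
        Target lattice.

    A voxel is occupied iff its centre lies inside an odd number of that
    slice's polygons (even-odd rule).
    """
    occ = np.zeros(grid.dims, dtype=bool)
    if not contours:
        return StructureMask(label, grid, occ)

    xs, ys, _ = grid.coordinate_axes()
    # voxel-centre lattice of one slice, shape (nx*ny, 2)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])

    sz = grid.spacing[2]
    for c in contours:
        pts = np.asarray(c, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
            raise ValueError("each contour must be an (N>=3, 3) coordinate array")
        z = pts[:, 2]
        if np.ptp(z) > 1e-6:
            raise ValueError("contour is not planar in z")
        k_float = (z[0] - grid.origin[2]) / sz
        k = int(round(k_float))
        if k < 0 or k >= grid.dims[2] or abs(k_float - k) > 0.5 + 1e-9:
            raise ValueError(
                f"contour plane z={z[0]:.3f} mm does not align with any grid "
                f"slice within half a slice spacing ({sz / 2:.3f} mm)"
            )
        # Path(closed=True) treats the final vertex as the CLOSEPOLY
        # placeholder, so the first vertex must be repeated explicitly
        ring = np.vstack([pts[:, :2], pts[:1, :2]])
        inside = _MplPath(ring, closed=True).contains_points(centers)
        # even-odd across multiple polygons on a slice: XOR of containments
        occ[:, :, k] ^= inside.reshape(grid.dims[0], grid.dims[1])

    return StructureMask(label, grid, occ)


# ----------------------------------------------------------------------
# measurements and morphology
# ----------------------------------------------------------------------

def volume_cc(mask: StructureMask) -> float:
    """Structure volume in cubic centimetres (voxel count x voxel volume)."""
    return mask.volume_cc()


def expand_mask(mask: StructureMask, margin_mm: float, label: str | None = None) -> StructureMask:
    """Isotropic Euclidean expansion by ``margin_mm`` (CTV -> PTV margin).

    A voxel is occupied in the result iff its centre lies within
    ``margin_mm`` of the nearest occupied input voxel centre, with
    anisotropic spacing respected.  The result is a superset of the input.
    """
    if margin_mm < 0:
        raise ValueError(f"margin must be >= 0, got {margin_mm}")
    if margin_mm == 0 or mask.is_empty:
        return mask.copy(label)
    dist = ndimage.distance_transform_edt(~mask.occupancy, sampling=mask.grid.spacing)
    return StructureMask(label or mask.label, mask.grid, dist <= margin_mm)


def union(masks: list[StructureMask], label: str = "union") -> StructureMask:
    """Voxelwise logical OR of masks sharing one grid (structure grouping)."""
    if not masks:
        raise ValueError("union of no masks is undefined")
    grid = masks[0].grid
    occ = np.zeros(grid.dims, dtype=bool)
    for m in masks:
        if not m.grid.matches(grid):
            raise ValueError(f"mask {m.label!r} is on a different grid")
        occ |= m.occupancy
    return StructureMask(label, grid, occ)


def intersection(masks: list[StructureMask], label: str = "intersection") -> StructureMask:
    """Voxelwise logical AND of masks sharing one grid."""
    if not masks:
        raise ValueError("intersection of no masks is undefined")
    grid = masks[0].grid
    occ = np.ones(grid.dims, dtype=bool)
    for m in masks:
        if not m.grid.matches(grid):
            raise ValueError(f"mask {m.label!r} is on a different grid")
        occ &= m.occupancy
    return StructureMask(label, grid, occ)


def subtract(a: StructureMask, b: StructureMask, label: str | None = None) -> StructureMask:
    """Voxels of ``a`` not occupied by ``b``."""
    if not a.grid.matches(b.grid):
        raise ValueError("masks are on different grids")
    return StructureMask(label or a.label, a.grid, a.occupancy & ~b.occupancy)


def border_extents(mask: StructureMask, laterality: str = "left") -> BorderExtents:
    """Cranial/caudal/medial/lateral borders of a structure in world mm.

    Cranial = maximum z, caudal = minimum z over occupied voxel centres.
    For ``laterality='left'`` the lateral border is the maximum x and the
    medial border the minimum x (mirrored for ``'right'``).
    """
    if laterality not in ("left", "right"):
        raise ValueError(f"laterality must be 'left' or 'right', got {laterality!r}")
    if mask.is_empty:
        raise EmptyMaskError(f"structure {mask.label!r} has no occupied voxels")
    centers = mask.occupied_centers()
    zmin, zmax = centers[:, 2].min(), centers[:, 2].max()
    xmin, xmax = centers[:, 0].min(), centers[:, 0].max()
    if laterality == "left":
        medial, lateral = xmin, xmax
    else:
        medial, lateral = xmax, xmin
    return BorderExtents(
        cranial_mm=float(zmax),
        caudal_mm=float(zmin),
        medial_mm=float(medial),
        lateral_mm=float(lateral),
        laterality=laterality,
    )


def border_difference_table(
    sets: list[StructureSet],
    label: str,
    borders: tuple[str, ...] = ("cranial", "caudal", "medial", "lateral"),
    laterality: str = "left",
) -> dict[str, float]:
    """Maximum pairwise inter-observer border difference per border, in cm.

    Observers missing the requested structure are skipped with a warning.
    """
    valid = {"cranial", "caudal", "medial", "lateral"}
    bad = set(borders) - valid
    if bad:
        raise ValueError(f"unknown borders {sorted(bad)}")
    extents = []
    for s in sets:
        if label not in s:
            logger.warning(
                "observer %s has no structure %r; skipped from border comparison",
                s.observer_id, label,
            )
            continue
        extents.append(border_extents(s[label], laterality).as_dict())
    if len(extents) < 2:
        raise ValueError(
            f"need at least 2 observers with structure {label!r}, got {len(extents)}"
        )
    out: dict[str, float] = {}
    for b in borders:
        vals = np.array([e[b] for e in extents])
        out[b] = float(vals.max() - vals.min()) / 10.0  # mm -> cm
    return out


def resample_mask(mask: StructureMask, target: VoxelGrid) -> StructureMask:
    """Nearest-neighbour resampling of a binary mask onto a reference grid.

    Target voxel centres falling outside the source lattice are unoccupied.
    """
    if mask.grid.matches(target):
        return mask.copy()
    axes = [
        np.round((t_ax - mask.grid.origin[a]) / mask.grid.spacing[a]).astype(int)
        for a, t_ax in enumerate(target.coordinate_axes())
    ]
    valid = [
        (ax >= 0) & (ax < mask.grid.dims[a]) for a, ax in enumerate(axes)
    ]
    occ = np.zeros(target.dims, dtype=bool)
    ii = np.clip(axes[0], 0, mask.grid.dims[0] - 1)
    jj = np.clip(axes[1], 0, mask.grid.dims[1] - 1)
    kk = np.clip(axes[2], 0, mask.grid.dims[2] - 1)
    occ[:] = mask.occupancy[np.ix_(ii, jj, kk)]
    occ &= valid[0][:, None, None] & valid[1][None, :, None] & valid[2][None, None, :]
    return StructureMask(mask.label, target, occ)
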