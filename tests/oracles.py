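"""Independent brute-force oracles and geometry helpers used by the tests.

Everything here is deliberately written as straight loops / direct numpy
reductions, organized differently from the package implementation, so that
agreement between the two is meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from rtcompare import StructureMask, VoxelGrid
from rtcompare.surface import extract_surface


# ----------------------------------------------------------------------
# geometry builders
# ----------------------------------------------------------------------

def sphere_mask(grid: VoxelGrid, center, radius_mm: float, label: str = "sphere") -> StructureMask:
    """Ball rasterized by voxel-centre containment."""
    x, y, z = grid.coordinate_axes()
    occ = (
        (x[:, None, None] - center[0]) ** 2
        + (y[None, :, None] - center[1]) ** 2
        + (z[None, None, :] - center[2]) ** 2
        <= radius_mm ** 2
    )
    return StructureMask(label, grid, occ)


def box_mask(grid: VoxelGrid, lo_idx, hi_idx, label: str = "box") -> StructureMask:
    """Axis-aligned box of voxels with indices lo_idx..hi_idx inclusive."""
    occ = np.zeros(grid.dims, dtype=bool)
    sl = tuple(slice(a, b + 1) for a, b in zip(lo_idx, hi_idx))
    occ[sl] = True
    return StructureMask(label, grid, occ)


def random_blob(grid: VoxelGrid, rng: np.random.Generator, label: str = "blob") -> StructureMask:
    """Random connected-ish blob: thresholded smoothed noise, never empty."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.standard_normal(grid.dims), sigma=2.0)
    occ = field > np.quantile(field, 0.85)
    if not occ.any():
        occ[tuple(d // 2 for d in grid.dims)] = True
    return StructureMask(label, grid, occ)


# ----------------------------------------------------------------------
# surface-dice oracle (O(n^2) pairwise distances)
# ----------------------------------------------------------------------

def sdsc_oracle(mask_a: StructureMask, mask_b: StructureMask, tolerance_mm: float) -> float:
    surf_a = extract_surface(mask_a)
    surf_b = extract_surface(mask_b)
    d = cdist(surf_a.positions, surf_b.positions)
    within_a = surf_a.areas[d.min(axis=1) <= tolerance_mm].sum()
    within_b = surf_b.areas[d.min(axis=0) <= tolerance_mm].sum()
    return float((within_a + within_b) / (surf_a.total_area + surf_b.total_area))


# ----------------------------------------------------------------------
# point-in-polygon oracle (ray casting, even-odd)
# ----------------------------------------------------------------------

def point_in_polygon(px: float, py: float, poly: np.ndarray) -> bool:
    """Even-odd ray casting; poly is an (N, 2) closed polygon (implicit edge)."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


# ----------------------------------------------------------------------
# DVH metric oracles (direct counting / sorting)
# ----------------------------------------------------------------------

def dmean_oracle(dose: np.ndarray, occ: np.ndarray) -> float:
    total = 0.0
    n = 0
    for v in dose[occ].ravel():
        total += v
        n += 1
    return total / n


def vdose_oracle(dose: np.ndarray, occ: np.ndarray, threshold_gy: float,
                 voxel_cc: float, output: str) -> float:
    n = sum(1 for v in dose[occ].ravel() if v >= threshold_gy)
    if output == "cc":
        return n * voxel_cc
    return 100.0 * n / int(occ.sum())


def dpercent_oracle(dose: np.ndarray, occ: np.ndarray, p: float, prescription: float) -> float:
    vals = sorted(dose[occ].ravel(), reverse=True)
    k = int(np.ceil(p / 100.0 * len(vals)))
    return 100.0 * vals[k - 1] / prescription


def icru_oracle(dose: np.ndarray, body: np.ndarray, prescription: float,
                voxel_cc: float) -> tuple[float, float]:
    vals = dose[body].ravel()
    treated = sum(1 for v in vals if v >= 0.9 * prescription) * voxel_cc
    irradiated = sum(1 for v in vals if v >= 0.5 * prescription) * voxel_cc
    return treated, irradiated


def outside_ptv_oracle(dose: np.ndarray, ptv: np.ndarray, body: np.ndarray,
                       prescription: float, voxel_cc: float) -> float:
    region = body & ~ptv
    return sum(1 for v in dose[region].ravel() if v > 0.9 * prescription) * voxel_cc
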