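"""File I/O: NIfTI volumes for masks and dose, DICOM RT Structure Set import.

NIfTI affines are restricted to axis-aligned (diagonal) geometries with
positive spacing, matching the package's grid model; oblique volumes are
rejected with a clear diagnostic rather than silently re-oriented.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .grid import VoxelGrid
from .mask import StructureMask, StructureSet, rasterize_polygons

__all__ = [
    "read_mask_volume",
    "write_mask_volume",
    "read_dose_volume",
    "write_dose_volume",
    "read_rtstruct",
]

logger = logging.getLogger(__name__)


def _grid_to_affine(grid: VoxelGrid) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin
    return affine


def _affine_to_grid(affine: np.ndarray, shape: tuple[int, ...]) -> VoxelGrid:
    rot = np.asarray(affine)[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.abs(off_diag).max() > 1e-6 * max(1.0, np.abs(rot).max()):
        raise ValueError("oblique NIfTI affines are not supported; resample first")
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise ValueError(
            "NIfTI affine has non-positive diagonal spacing; flip axes before import"
        )
    return VoxelGrid(tuple(shape[:3]), tuple(spacing), tuple(np.asarray(affine)[:3, 3]))


def write_mask_volume(mask: StructureMask, path: str | Path) -> None:
    """Write a binary mask as a uint8 NIfTI volume."""
    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), _grid_to_affine(mask.grid))
    nib.save(img, str(path))


def read_mask_volume(
    path: str | Path,
    label: str | None = None,
    threshold: float | None = None,
) -> StructureMask:
    """Read a binary mask from NIfTI; nonzero voxels become occupied.

    Non-binary volumes are accepted only when ``threshold`` is given, in
    which case voxels with ``value > threshold`` are occupied.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    grid = _affine_to_grid(img.affine, data.shape)
    if threshold is not None:
        occ = data > threshold
    else:
        vals = np.unique(data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(
                f"{path}: volume is not binary; pass an explicit threshold"
            )
        occ = data != 0
    return StructureMask(label or Path(str(path)).stem.replace(".nii", ""), grid, occ)


def write_dose_volume(dose, path: str | Path) -> None:
    """Write a dose grid (Gy per voxel) as a float32 NIfTI volume."""
    img = nib.Nifti1Image(dose.dose.astype(np.float32), _grid_to_affine(dose.grid))
    nib.save(img, str(path))


def read_dose_volume(path: str | Path, prescription_gy: float, n_fractions: int):
    """Read an absolute dose volume (Gy) from NIfTI."""
    from .dosimetry import DoseGrid

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    grid = _affine_to_grid(img.affine, data.shape)
    return DoseGrid(grid, data, prescription_gy, n_fractions)


def read_rtstruct(
    path: str | Path,
    grid: VoxelGrid,
    observer_id: str = "rtstruct",
    labels: list[str] | None = None,
) -> StructureSet:
    """Rasterize a DICOM RT Structure Set's polygon contours onto a grid.

    Only CLOSED_PLANAR contour geometry is supported; contour points are
    taken as world mm in the package's axis convention.
    """
    ds = pydicom.dcmread(str(path), force=True)
    if "StructureSetROISequence" not in ds or "ROIContourSequence" not in ds:
        raise ValueError(f"{path}: not an RT Structure Set (missing ROI sequences)")
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    out = StructureSet(observer_id)
    for roi in ds.ROIContourSequence:
        name = names.get(int(roi.ReferencedROINumber), f"roi{roi.ReferencedROINumber}")
        if labels is not None and name not in labels:
            continue
        contours = []
        for c in getattr(roi, "ContourSequence", []):
            geom = str(getattr(c, "ContourGeometricType", "CLOSED_PLANAR"))
            if geom != "CLOSED_PLANAR":
                logger.warning("%s: skipping %s contour in %r", path, geom, name)
                continue
            pts = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            contours.append(pts)
        out.add(rasterize_polygons(contours, grid, label=name))
    return out
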