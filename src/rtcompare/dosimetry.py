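"""DVH engine and the dose-metric catalogue for plan evaluation.

Covers the metrics used in national breast-radiotherapy audits: Dmean, VxGy
(as % of structure or absolute cc), V105% of prescription, D98% coverage,
ICRU-50 treated (>=90% of prescription) and irradiated (>=50%) volumes, the
irradiated volume outside the PTV, and pass/fail coverage verdicts against
guideline thresholds.

All metrics count whole voxels (no partial-volume weighting) so every value
is reproducible by a direct voxel-counting or sorting oracle.  Dose is
resampled to the structure grid, never the reverse: the structures define
the analysis frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid
from .mask import EmptyMaskError, StructureMask, subtract

__all__ = [
    "DoseGrid",
    "DVHCurve",
    "CoverageVerdict",
    "DEFAULT_COVERAGE_CRITERIA",
    "resample_dose",
    "compute_dvh",
    "d_mean",
    "v_dose",
    "d_percent_coverage",
    "icru_volumes",
    "irradiated_outside_ptv",
    "coverage_report",
]

logger = logging.getLogger(__name__)

#: Guideline coverage thresholds: structure label -> required D98% as % of
#: prescription (CTV breast + nodal volumes 95%, internal mammary chain 90%,
#: PTV 93%).
DEFAULT_COVERAGE_CRITERIA: dict[str, float] = {
    "CTV-breast+CTVN": 95.0,
    "CTV-IMN": 90.0,
    "PTV-breast+PTVN": 93.0,
}


@dataclass
class DoseGrid:
    """Absolute dose in Gy per voxel with its prescription context."""

    grid: VoxelGrid
    dose: np.ndarray
    prescription_gy: float
    n_fractions: int = 15

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.grid.dims:
            raise ValueError("dose shape does not match grid dims")
        if np.any(self.dose < 0):
            raise ValueError("dose must be nonnegative everywhere")
        if self.prescription_gy <= 0:
            raise ValueError("prescription dose must be positive")
        if self.n_fractions < 1:
            raise ValueError("fraction count must be a positive integer")

    def scaled(self, factor: float) -> "DoseGrid":
        """Same plan with every voxel dose multiplied by ``factor``."""
        return DoseGrid(self.grid, self.dose * factor, self.prescription_gy, self.n_fractions)


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure."""

    label: str
    total_cc: float
    dose_gy: np.ndarray       # thresholds, ascending
    volume_cc: np.ndarray     # structure volume at-or-above each threshold
    volume_pct: np.ndarray    # same, as % of structure volume


@dataclass(frozen=True)
class CoverageVerdict:
    """One guideline criterion evaluated on one structure."""

    structure: str
    metric: str
    threshold_pct: float
    achieved_pct: float | None
    passed: bool | None
    evaluable: bool = True


def _masked_dose(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    if not dose.grid.matches(mask.grid):
        raise ValueError(
            "dose and structure are on different grids; resample the dose "
            "to the structure grid first"
        )
    return dose.dose[mask.occupancy]


def resample_dose(dose: DoseGrid, target: VoxelGrid) -> DoseGrid:
    """Trilinear resampling of a dose grid onto a structure grid.

    Target voxel centres outside the source extent receive 0 Gy with a
    logged warning; spatially disjoint grids are rejected.
    """
    if dose.grid.matches(target):
        return DoseGrid(target, dose.dose.copy(), dose.prescription_gy, dose.n_fractions)
    src_lo, src_hi = dose.grid.bounds()
    tgt_lo, tgt_hi = target.bounds()
    if np.any(tgt_hi < src_lo) or np.any(tgt_lo > src_hi):
        raise ValueError("dose grid and target grid do not overlap spatially")
    axes = target.coordinate_axes()
    frac = [
        (ax - dose.grid.origin[a]) / dose.grid.spacing[a] for a, ax in enumerate(axes)
    ]
    ii, jj, kk = np.meshgrid(*frac, indexing="ij")
    coords = np.stack([ii, jj, kk])
    out = ndimage.map_coordinates(dose.dose, coords, order=1, mode="constant", cval=0.0)
    outside = [
        np.any((f < 0) | (f > dose.grid.dims[a] - 1)) for a, f in enumerate(frac)
    ]
    if any(outside):
        logger.warning("target grid extends outside the dose extent; padded with 0 Gy")
    return DoseGrid(target, out, dose.prescription_gy, dose.n_fractions)


def compute_dvh(dose: DoseGrid, mask: StructureMask, bin_width_gy: float = 0.01) -> DVHCurve:
    """Cumulative at-or-above DVH over the structure's voxels."""
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    vals = _masked_dose(dose, mask)
    if vals.size == 0:
        raise EmptyMaskError(f"structure {mask.label!r} is empty; DVH undefined")
    vmax = float(vals.max())
    thresholds = np.arange(0.0, vmax + 2 * bin_width_gy, bin_width_gy)
    # volume at-or-above t = (# voxels >= t) * voxel volume
    sorted_vals = np.sort(vals)
    n_below = np.searchsorted(sorted_vals, thresholds, side="left")
    n_at_or_above = vals.size - n_below
    vol_cc = n_at_or_above * mask.grid.voxel_volume_cc
    total = mask.volume_cc()
    return DVHCurve(mask.label, total, thresholds, vol_cc, 100.0 * vol_cc / total)


def d_mean(dose: DoseGrid, mask: StructureMask) -> float:
    """Arithmetic mean dose (Gy) over the structure's voxels."""
    vals = _masked_dose(dose, mask)
    if vals.size == 0:
        raise EmptyMaskError(f"structure {mask.label!r} is empty; Dmean undefined")
    return float(vals.mean())


def _resolve_threshold_gy(threshold, prescription_gy: float) -> float:
    """Accept a threshold in Gy (number) or as % of prescription ('105%')."""
    if isinstance(threshold, str):
        t = threshold.strip()
        if not t.endswith("%"):
            raise ValueError(f"cannot parse threshold {threshold!r}; use Gy or 'NN%'")
        return float(t[:-1]) / 100.0 * prescription_gy
    return float(threshold)


def v_dose(dose: DoseGrid, mask: StructureMask, threshold, output: str = "percent") -> float:
    """VxGy: structure volume at-or-above a dose threshold.

    ``threshold`` is either Gy (number) or a percentage of the prescription
    (string, e.g. ``"105%"``).  ``output`` selects % of structure volume or
    absolute cc.  The comparison is inclusive (>=).
    """
    if output not in ("percent", "cc"):
        raise ValueError(f"output must be 'percent' or 'cc', got {output!r}")
    t = _resolve_threshold_gy(threshold, dose.prescription_gy)
    vals = _masked_dose(dose, mask)
    if vals.size == 0:
        if output == "percent":
            raise EmptyMaskError(
                f"structure {mask.label!r} is empty; percent volume undefined"
            )
        return 0.0
    n = int(np.count_nonzero(vals >= t))
    if output == "cc":
        return n * mask.grid.voxel_volume_cc
    return 100.0 * n / vals.size


def d_percent_coverage(dose: DoseGrid, mask: StructureMask, p: float = 98.0) -> float:
    """D_p%: the dose received by at least p% of the structure volume,
    expressed as % of the prescription dose.

    Computed by exact sorting (not from a binned DVH): with n voxels sorted
    by descending dose, D_p% is the ``ceil(p/100 * n)``-th highest dose.
    """
    if not (0 < p <= 100):
        raise ValueError(f"volume percentile must be in (0, 100], got {p}")
    vals = _masked_dose(dose, mask)
    if vals.size == 0:
        raise EmptyMaskError(f"structure {mask.label!r} is empty; D{p}% undefined")
    k = int(np.ceil(p / 100.0 * vals.size))
    d = np.sort(vals)[::-1][k - 1]
    return float(100.0 * d / dose.prescription_gy)


def icru_volumes(dose: DoseGrid, body: StructureMask) -> tuple[float, float]:
    """ICRU-50 treated and irradiated volumes within the body, in cc.

    Treated volume: body volume receiving >= 90% of the prescription.
    Irradiated volume: body volume receiving >= 50% of the prescription.
    """
    if body.is_empty:
        raise EmptyMaskError("body structure is empty")
    vals = _masked_dose(dose, body)
    vv = body.grid.voxel_volume_cc
    treated = float(np.count_nonzero(vals >= 0.9 * dose.prescription_gy) * vv)
    irradiated = float(np.count_nonzero(vals >= 0.5 * dose.prescription_gy) * vv)
    return treated, irradiated


def irradiated_outside_ptv(dose: DoseGrid, ptv: StructureMask, body: StructureMask) -> float:
    """Normal-tissue volume (cc) outside the PTV receiving > 90% of the
    prescription dose (strictly greater, per the guideline wording);
    evaluated within the body after intersecting the PTV with it."""
    inside_body_ptv = StructureMask(ptv.label, ptv.grid, ptv.occupancy & body.occupancy)
    region = subtract(body, inside_body_ptv, label="body-minus-ptv")
    vals = _masked_dose(dose, region)
    return float(np.count_nonzero(vals > 0.9 * dose.prescription_gy)
                 * region.grid.voxel_volume_cc)


def coverage_report(
    dose: DoseGrid,
    structures: dict[str, StructureMask],
    criteria: dict[str, float] | None = None,
) -> list[CoverageVerdict]:
    """Evaluate D98% guideline criteria; pass iff achieved >= threshold.

    ``criteria`` maps structure label -> required D98% (% of prescription).
    Structures missing from ``structures`` yield a not-evaluable verdict.
    """
    criteria = DEFAULT_COVERAGE_CRITERIA if criteria is None else criteria
    verdicts = []
    for label, threshold in criteria.items():
        if label not in structures or structures[label].is_empty:
            logger.warning("structure %r missing or empty; criterion not evaluable", label)
            verdicts.append(CoverageVerdict(label, "D98%", threshold, None, None, False))
            continue
        achieved = d_percent_coverage(dose, structures[label], 98.0)
        verdicts.append(
            CoverageVerdict(label, "D98%", threshold, achieved, achieved >= threshold)
        )
    return verdicts
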