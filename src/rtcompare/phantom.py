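"""Synthetic phantom cohort: anatomy, observer variability, and dose.

The study conditions this package analyses require a CT-like structure set
(left-sided breast target, axillary/supraclavicular node levels, internal
mammary chain, and the thoracic organs at risk), several observers'
delineations of the targets, and a planned dose distribution.  This module
generates all three:

* :func:`make_phantom` builds a deterministic anthropomorphic phantom from
  analytic shapes (elliptic-cylinder body, hemi-ellipsoid breast, ellipsoid
  node cluster, tubular parasternal chain, ellipsoid organs at risk) with
  default dimensions chosen so target volumes are of the clinical order
  (breast CTV ~850 cc, grouped nodal CTV ~100 cc, IMN CTV ~6 cc).
* :class:`ObserverSimulator` / :func:`perturb_observer` emulate
  inter-observer delineation variability by displacing each target's
  boundary with a smooth correlated random field.
* :func:`synthetic_dose` is an idealized plan model: the PTV indicator
  blurred by an anisotropic Gaussian penumbra elongated along the beam axis
  (lateral-oblique for tangential fields, anterior-posterior for AP-PA),
  plus a low dose bath inside the body.  It is not a beam-transport model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.special import ndtr

from .dosimetry import DoseGrid
from .grid import VoxelGrid
from .mask import StructureMask, StructureSet, expand_mask, union

__all__ = [
    "PhantomSpec",
    "ObserverNoiseSpec",
    "ObserverSimulator",
    "TARGET_LABELS",
    "NODE_LABELS",
    "OAR_LABELS",
    "make_phantom",
    "perturb_observer",
    "synthetic_dose",
]

#: Node-level labels that group into the nodal CTV (levels I-IV + interpectoral).
NODE_LABELS: tuple[str, ...] = (
    "LN-level1", "LN-level2", "LN-level3", "LN-level4", "LN-interpectoral",
)

#: Structures observers delineate (and that observer noise perturbs).
TARGET_LABELS: tuple[str, ...] = ("CTV-breast",) + NODE_LABELS + ("CTV-IMN",)

OAR_LABELS: tuple[str, ...] = (
    "heart", "lung-ipsilateral", "lung-contralateral", "breast-contralateral",
    "esophagus", "thyroid", "humeral-head",
)


def _default_nodes() -> dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]]:
    # label -> (center mm, semiaxes mm); axillary level I lateral/caudal up to
    # the supraclavicular level IV cranial/medial, plus the interpectoral node.
    return {
        "LN-level1": ((105.0, -10.0, 225.0), (20.0, 18.0, 24.0)),
        "LN-level2": ((85.0, -5.0, 240.0), (16.0, 14.0, 20.0)),
        "LN-level3": ((65.0, -10.0, 252.0), (14.0, 13.0, 18.0)),
        "LN-level4": ((40.0, -15.0, 268.0), (18.0, 13.0, 18.0)),
        "LN-interpectoral": ((80.0, -30.0, 235.0), (11.0, 11.0, 15.0)),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic thorax phantom (all lengths in mm).

    The default grid is 2.5 mm isotropic over a 360 x 260 x 340 mm field of
    view.  Structure centres/semiaxes are given for a left-sided case; for
    ``laterality='right'`` every x coordinate is mirrored about the midline.
    """

    dims: tuple[int, int, int] = (144, 104, 136)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    origin: tuple[float, float, float] = (-180.0, -130.0, 0.0)
    laterality: str = "left"

    # body: elliptic cylinder plus the breast bulge
    body_semiaxes_xy: tuple[float, float] = (150.0, 80.0)
    body_center_y: float = 10.0
    body_z_mm: tuple[float, float] = (5.0, 335.0)
    breast_bulge_margin_mm: float = 7.0

    # targets; the breast is the part of its ellipsoid anterior to the
    # chest-wall ellipse (the body cylinder's surface), so its posterior
    # surface is curved like a real residual breast on the thoracic wall
    breast_center: tuple[float, float, float] = (62.0, -63.0, 150.0)
    breast_semiaxes: tuple[float, float, float] = (62.0, 58.0, 103.0)
    nodes: dict = field(default_factory=_default_nodes)
    imn_center_xy: tuple[float, float] = (20.0, -55.0)
    imn_radius_mm: float = 5.0
    imn_z_mm: tuple[float, float] = (140.0, 215.0)

    # organs at risk
    heart_center: tuple[float, float, float] = (15.0, 15.0, 135.0)
    heart_semiaxes: tuple[float, float, float] = (45.0, 35.0, 50.0)
    lung_center: tuple[float, float, float] = (70.0, 15.0, 190.0)
    lung_semiaxes: tuple[float, float, float] = (55.0, 60.0, 105.0)
    contra_breast_center: tuple[float, float, float] = (-60.0, -50.0, 150.0)
    contra_breast_semiaxes: tuple[float, float, float] = (50.0, 45.0, 75.0)
    esophagus_center_xy: tuple[float, float] = (0.0, 35.0)
    esophagus_radius_mm: float = 8.0
    esophagus_z_mm: tuple[float, float] = (60.0, 300.0)
    thyroid_center: tuple[float, float, float] = (0.0, -40.0, 305.0)
    thyroid_semiaxes: tuple[float, float, float] = (22.0, 12.0, 15.0)
    humeral_center: tuple[float, float, float] = (125.0, -5.0, 290.0)
    humeral_radius_mm: float = 20.0

    def __post_init__(self) -> None:
        if self.laterality not in ("left", "right"):
            raise ValueError("laterality must be 'left' or 'right'")

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(self.dims, self.spacing, self.origin)

    def _mirror(self, x: float) -> float:
        return x if self.laterality == "left" else -x


@dataclass(frozen=True)
class ObserverNoiseSpec:
    """Boundary-noise parameters for one simulated observer.

    ``sigma_mm`` is the mean absolute boundary displacement; the displacement
    field is smooth with correlation length ``correlation_mm``, emulating the
    systematic, spatially coherent way human observers deviate from a
    reference contour (never voxel speckle).
    """

    sigma_mm: float
    correlation_mm: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_mm < 0:
            raise ValueError("sigma_mm must be >= 0")
        if self.correlation_mm <= 0:
            raise ValueError("correlation_mm must be > 0")


# ----------------------------------------------------------------------
# phantom construction
# ----------------------------------------------------------------------

def _axes(grid: VoxelGrid):
    x, y, z = grid.coordinate_axes()
    return x[:, None, None], y[None, :, None], z[None, None, :]


def _ellipsoid(grid, center, semiaxes) -> np.ndarray:
    x, y, z = _axes(grid)
    cx, cy, cz = center
    a, b, c = semiaxes
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0


def _tube_z(grid, center_xy, radius, z_mm) -> np.ndarray:
    x, y, z = _axes(grid)
    cx, cy = center_xy
    return (((x - cx) ** 2 + (y - cy) ** 2) <= radius ** 2) & (z >= z_mm[0]) & (z <= z_mm[1])


def _elliptic_cylinder(grid, center_xy, semiaxes_xy, z_mm) -> np.ndarray:
    x, y, z = _axes(grid)
    cx, cy = center_xy
    a, b = semiaxes_xy
    return (((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0) & (z >= z_mm[0]) & (z <= z_mm[1])


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> StructureSet:
    """Build the deterministic reference observer's structure set.

    Raises if a structure reaches the grid's outer voxel layer (it would be
    silently truncated) or if any target is not contained in the body.
    """
    grid = spec.grid
    m = spec._mirror

    def mirror3(c):
        return (m(c[0]), c[1], c[2])

    # breasts first: each is its ellipsoid clipped to the tissue anterior to
    # the chest-wall ellipse; the body includes both anterior bulges
    x, y, _ = _axes(grid)
    a_b, b_b = spec.body_semiaxes_xy
    outside_chest_wall = np.broadcast_to(
        (x / a_b) ** 2 + ((y - spec.body_center_y) / b_b) ** 2 >= 1.0, grid.dims
    )
    bc = mirror3(spec.breast_center)
    breast = _ellipsoid(grid, bc, spec.breast_semiaxes) & outside_chest_wall
    cbc = mirror3(spec.contra_breast_center)
    cbreast = _ellipsoid(grid, cbc, spec.contra_breast_semiaxes) & outside_chest_wall

    body = _elliptic_cylinder(
        grid, (0.0, spec.body_center_y), spec.body_semiaxes_xy, spec.body_z_mm
    )
    bulge = expand_mask(
        StructureMask("breasts", grid, breast | cbreast), spec.breast_bulge_margin_mm
    ).occupancy
    body |= bulge

    masks: dict[str, np.ndarray] = {"body": body, "CTV-breast": breast}

    for label, (center, semiaxes) in spec.nodes.items():
        masks[label] = _ellipsoid(grid, mirror3(center), semiaxes)
    masks["CTV-IMN"] = _tube_z(
        grid, (m(spec.imn_center_xy[0]), spec.imn_center_xy[1]),
        spec.imn_radius_mm, spec.imn_z_mm,
    )

    heart = _ellipsoid(grid, mirror3(spec.heart_center), spec.heart_semiaxes)
    masks["heart"] = heart
    lung_i = _ellipsoid(grid, mirror3(spec.lung_center), spec.lung_semiaxes) & ~heart
    lc = spec.lung_center
    lung_c = _ellipsoid(grid, (m(-lc[0]), lc[1], lc[2]), spec.lung_semiaxes) & ~heart
    masks["lung-ipsilateral"] = lung_i
    masks["lung-contralateral"] = lung_c
    masks["breast-contralateral"] = cbreast
    masks["esophagus"] = _tube_z(
        grid, spec.esophagus_center_xy, spec.esophagus_radius_mm, spec.esophagus_z_mm
    )
    masks["thyroid"] = _ellipsoid(grid, mirror3(spec.thyroid_center), spec.thyroid_semiaxes)
    hc = mirror3(spec.humeral_center)
    masks["humeral-head"] = _ellipsoid(
        grid, hc, (spec.humeral_radius_mm,) * 3
    )

    out = StructureSet("reference")
    for label, occ in masks.items():
        if not occ.any():
            raise ValueError(f"phantom structure {label!r} rasterized to an empty mask")
        edge = (
            occ[0].any() or occ[-1].any()
            or occ[:, 0].any() or occ[:, -1].any()
            or occ[:, :, 0].any() or occ[:, :, -1].any()
        )
        if edge:
            raise ValueError(f"phantom structure {label!r} extends outside the grid")
        out.add(StructureMask(label, grid, occ))

    for label in TARGET_LABELS:
        if np.any(out[label].occupancy & ~body):
            raise ValueError(f"target {label!r} is not contained in the body")
    return out


# ----------------------------------------------------------------------
# observer variability
# ----------------------------------------------------------------------

# scale factor so that sigma_mm is the MEAN ABSOLUTE displacement of a
# unit-variance Gaussian field (E|N(0,1)| = sqrt(2/pi))
_MEAN_ABS_SCALE = math.sqrt(math.pi / 2.0)


class ObserverSimulator:
    """Generate perturbed observers from one reference structure set.

    Each target's boundary is displaced by thresholding the reference's
    signed distance against a smooth spatially correlated random field: a
    voxel is occupied when ``signed_distance <= displacement_field``.  The
    field is one per observer (shared across that observer's structures,
    emulating a systematic contouring tendency), has unit variance, and is
    scaled so the mean absolute boundary displacement equals ``sigma_mm``.

    The signed distance of each reference label is computed once and reused
    for every observer, which keeps large cohorts cheap.
    """

    def __init__(self, reference: StructureSet, labels: tuple[str, ...] | None = None):
        self.reference = reference
        self.grid = reference.grid
        self.labels = tuple(
            lb for lb in (labels or TARGET_LABELS) if lb in reference
        )
        spacing = self.grid.spacing
        self._signed: dict[str, np.ndarray] = {}
        for lb in self.labels:
            occ = reference[lb].occupancy
            inside = ndimage.distance_transform_edt(occ, sampling=spacing)
            outside = ndimage.distance_transform_edt(~occ, sampling=spacing)
            self._signed[lb] = outside - inside  # negative inside

    def _unit_field(self, rng: np.random.Generator, correlation_mm: float) -> np.ndarray:
        white = rng.standard_normal(self.grid.dims)
        sigma_vox = [correlation_mm / s for s in self.grid.spacing]
        smooth = ndimage.gaussian_filter(white, sigma=sigma_vox)
        return smooth / smooth.std()

    def observer(self, noise: ObserverNoiseSpec, observer_id: str) -> StructureSet:
        out = StructureSet(observer_id)
        if noise.sigma_mm == 0:
            for lb, mk in self.reference.masks.items():
                out.add(mk.copy())
            return out
        rng = np.random.default_rng(noise.seed)
        disp = (_MEAN_ABS_SCALE * noise.sigma_mm) * self._unit_field(
            rng, noise.correlation_mm
        )
        for lb, mk in self.reference.masks.items():
            if lb not in self._signed:
                out.add(mk.copy())
                continue
            occ = self._signed[lb] <= disp
            if not occ.any():
                # a clinician never hands in an empty structure: keep the
                # deepest interior voxel when the displaced level set vanishes
                occ = occ.copy()
                occ[np.unravel_index(np.argmin(self._signed[lb]), occ.shape)] = True
            out.add(StructureMask(lb, self.grid, occ))
        return out

    def cohort(
        self,
        n_observers: int,
        sigma_mm: float,
        correlation_mm: float = 20.0,
        seed: int = 0,
    ) -> list[StructureSet]:
        """n independent observers at one noise level, seeded reproducibly."""
        root = np.random.SeedSequence(seed)
        return [
            self.observer(
                ObserverNoiseSpec(sigma_mm, correlation_mm, int(child.generate_state(1)[0] % (2**31))),
                observer_id=f"observer{i + 1:02d}",
            )
            for i, child in enumerate(root.spawn(n_observers))
        ]


def perturb_observer(
    reference: StructureSet,
    noise: ObserverNoiseSpec,
    observer_id: str = "observer",
    labels: tuple[str, ...] | None = None,
) -> StructureSet:
    """One perturbed observer; see :class:`ObserverSimulator`."""
    return ObserverSimulator(reference, labels).observer(noise, observer_id)


# ----------------------------------------------------------------------
# dose model
# ----------------------------------------------------------------------

def _shift(a: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros_like(a)
    src = []
    dst = []
    for d, o in enumerate(offset):
        n = a.shape[d]
        src.append(slice(max(0, -o), n - max(0, o)))
        dst.append(slice(max(0, o), n - max(0, -o)))
    out[tuple(dst)] = a[tuple(src)]
    return out


def synthetic_dose(
    ptv: StructureMask,
    body: StructureMask,
    technique: str = "tangential",
    prescription_gy: float = 40.05,
    n_fractions: int = 15,
    penumbra_mm: float = 6.0,
    bath_fraction: float = 0.02,
    elongation: float = 4.0,
    aperture_factor: float = 2.2,
    laterality: str = "left",
    beam_step_voxels: tuple[int, int, int] | None = None,
    midline_margin_mm: float | None = 15.0,
) -> DoseGrid:
    """Idealized planned dose: smoothed field aperture plus a body dose bath.

    The field aperture is the PTV (intersected with the body) expanded by
    ``aperture_factor * penumbra_mm`` isotropically and further extended
    along the beam axis — so that, as in a planned field, the penumbra falls
    outside the target.  The beam axis is chest-wall-tangential oblique for
    ``'tangential'`` (opposed breast fields, roughly parallel to the
    anterolateral body surface so the field edge grazes the thoracic wall)
    and anterior-posterior for ``'ap_pa'`` (opposed nodal fields); it can be
    overridden with ``beam_step_voxels``.  The aperture indicator is then
    blurred by an isotropic Gaussian of scale ``penumbra_mm`` followed by an
    extra 1-D Gaussian along the beam axis making the penumbra
    ``elongation`` times longer along the beam than across it.  A uniform
    Tangential fields are additionally collimated at the sternal midline, as
    in clinical practice: a sharp field edge (erf profile of width
    ``penumbra_mm``) is placed ``midline_margin_mm`` beyond the ``x = 0``
    plane on the contralateral side (``None`` disables the border; it never
    applies to ``'ap_pa'`` fields).  A uniform
    ``bath_fraction`` of the prescription is added inside the body; dose is
    identically zero outside the body.  Every voxel dose is bounded by
    ``prescription * (1 + bath_fraction)``.  With ``penumbra_mm = 0`` the
    dose is exactly the prescription inside the PTV and zero outside it
    (plus the bath).  Deterministic.
    """
    if technique not in ("tangential", "ap_pa"):
        raise ValueError(f"technique must be 'tangential' or 'ap_pa', got {technique!r}")
    if penumbra_mm < 0:
        raise ValueError("penumbra_mm must be >= 0")
    if not (0 <= bath_fraction < 1):
        raise ValueError("bath_fraction must be in [0, 1)")
    if elongation < 1:
        raise ValueError("elongation must be >= 1")
    if aperture_factor < 0:
        raise ValueError("aperture_factor must be >= 0")
    if laterality not in ("left", "right"):
        raise ValueError("laterality must be 'left' or 'right'")
    if midline_margin_mm is not None and midline_margin_mm < 0:
        raise ValueError("midline_margin_mm must be >= 0 or None")
    if not ptv.grid.matches(body.grid):
        raise ValueError("PTV and body must share one grid")

    grid = ptv.grid
    aperture = StructureMask("aperture", grid, ptv.occupancy & body.occupancy)
    if penumbra_mm > 0:
        if beam_step_voxels is not None:
            step = tuple(int(v) for v in beam_step_voxels)
        elif technique == "ap_pa":
            step = (0, 1, 0)
        else:
            step = (4 if laterality == "left" else -4, 1, 0)
        step_len = math.sqrt(sum((o * s) ** 2 for o, s in zip(step, grid.spacing)))
        sigma_extra = penumbra_mm * math.sqrt(max(elongation**2 - 1.0, 0.0))

        # field aperture: isotropic margin plus extension along the beam axis
        aperture = expand_mask(aperture, aperture_factor * penumbra_mm)
        occ = aperture.occupancy
        k_ap = int(math.ceil(aperture_factor * sigma_extra / step_len))
        grown = occ.copy()
        for k in range(1, k_ap + 1):
            grown |= _shift(occ, (step[0] * k, step[1] * k, step[2] * k))
            grown |= _shift(occ, (-step[0] * k, -step[1] * k, -step[2] * k))
        f = grown.astype(float)

        f = ndimage.gaussian_filter(f, sigma=[penumbra_mm / s for s in grid.spacing])
        if sigma_extra > 1e-9:
            k_max = max(1, int(math.ceil(3.5 * sigma_extra / step_len)))
            ks = np.arange(-k_max, k_max + 1)
            w = np.exp(-0.5 * (ks * step_len / sigma_extra) ** 2)
            w /= w.sum()
            g = np.zeros_like(f)
            for k, wk in zip(ks, w):
                g += wk * _shift(f, (step[0] * k, step[1] * k, step[2] * k))
            f = g
        if technique == "tangential" and midline_margin_mm is not None:
            # collimated medial field border: a sharp erf edge (width set by
            # the penumbra alone, not the along-beam elongation) at the
            # midline plane, offset toward the contralateral side
            xax = grid.coordinate_axes()[0]
            sign = 1.0 if laterality == "left" else -1.0
            edge = ndtr(sign * (xax + sign * midline_margin_mm) / penumbra_mm)
            f = f * edge[:, None, None]
    else:
        f = aperture.occupancy.astype(float)
    dose = prescription_gy * f
    dose += bath_fraction * prescription_gy
    dose *= body.occupancy
    return DoseGrid(grid, dose, prescription_gy, n_fractions)
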