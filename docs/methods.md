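# Methods

Definitions, parameter choices, and numerical conventions used throughout
`rtcompare`. All lengths are millimetres, volumes cubic centimetres, doses
Gray, unless stated otherwise.

## 1. Grid and mask conventions

A `VoxelGrid` is an axis-aligned lattice described by `dims`, `spacing`, and
`origin`; the world coordinate of voxel `(i, j, k)` is
`origin + index * spacing`, i.e. **the origin is the centre of the first
voxel**, and all containment tests are voxel-**centre** tests. Axes follow an
LPS-like convention: +x toward the patient's left, +y posterior, +z cranial.

A `StructureMask` is a boolean occupancy array over one grid; a
`StructureSet` is one observer's labelled collection of masks sharing a grid.
Volume is `voxel count × voxel volume` — no partial-volume weighting — so
every volume is reproducible by direct counting.

### Contour rasterization

Closed planar contours (e.g. from DICOM RT Structure Sets) are assigned to
the nearest grid slice (rejected if farther than half a slice spacing or not
planar) and filled by the even-odd rule on voxel centres. Multiple polygons
on one slice XOR together, so holes and islands behave as in treatment
planning systems.

### CTV → PTV expansion

`expand_mask` thresholds the Euclidean distance transform of the mask
complement (anisotropic spacing respected) at the margin: a voxel is occupied
iff its **centre** lies within `margin_mm` of an occupied input voxel
**centre**. This centre-to-centre definition is simple and exactly testable,
but carries an inherent digitization bias of up to half a voxel radially
(the continuous expansion of the underlying shape is slightly larger). At
1 mm spacing the bias on a 20 mm sphere expanded by 5 mm is ≈ 2%.

### Borders

Border extents are the extreme occupied-voxel-centre coordinates: cranial /
caudal = max / min z; lateral / medial = max / min x for a left-sided
structure (mirrored for right). Inter-observer border differences are the
maximum pairwise difference per border, reported in centimetres.

## 2. Consensus (mean structure)

Each voxel's agreement is the fraction of observers covering it; the
consensus mask keeps voxels with agreement ≥ 0.5. Implemented with integer
counts (`2 × count ≥ n`) so ties — e.g. 1 of 2 observers — are included
exactly, with no floating-point threshold ambiguity. The consensus is
permutation-invariant and always lies between the intersection and the union
of the inputs.

## 3. Surface dice similarity coefficient (sDSC)

The surface of a mask is the set of voxel **faces** between an occupied and
an unoccupied voxel (the grid boundary counts as unoccupied). Each face has
area equal to the product of the two in-plane spacings and a representative
point at its centre, halfway between the two voxel centres.

For masks A and B at tolerance τ, sDSC =
`(area of A's faces within τ of B's surface + area of B's faces within τ of A's surface) / (total area A + total area B)`,
with inclusive `≤ τ` comparison on exact nearest-neighbour Euclidean
distances (SciPy `cKDTree`). The measure is symmetric, bounded in [0, 1],
exactly 1 for identical masks at any τ ≥ 0, exactly 0 when the surfaces are
everywhere farther apart than τ, monotone in τ, and invariant to whole-voxel
translations. Because the face-centre distances are exact (no distance-map
quantization), an O(n²) brute-force oracle reproduces the implementation to
float round-off.

## 4. DVH engine

Dose lives on a `DoseGrid` (absolute Gy per voxel, with its prescription
context; default 40.05 Gy in 15 fractions). Dose is resampled **to the
structure grid** by trilinear interpolation — the structures define the
analysis frame — with 0 Gy padding outside the dose extent (warned) and
rejection of spatially disjoint grids.

All metrics count whole voxels:

- **Dmean** — arithmetic mean over the structure's voxels.
- **VxGy** — volume (percent of structure, or cc) at-or-above a threshold;
  threshold given in Gy or as a percentage of prescription (`"105%"`).
- **D98%** — exact sorting, not a binned DVH: with n voxels sorted by
  descending dose, D_p% is the `ceil(p/100 × n)`-th highest dose, reported
  as % of prescription.
- **ICRU treated / irradiated volume** — body volume at ≥ 90% / ≥ 50% of
  prescription (inclusive).
- **Volume outside the PTV above 90%** — body-minus-PTV volume with dose
  **strictly greater** than 0.9 × prescription, matching guideline wording.
- **Coverage verdicts** — D98% against per-structure thresholds (defaults:
  CTV-breast+CTVN 95%, CTV-IMN 90%, PTV-breast+PTVN 93%); missing or empty
  structures yield a not-evaluable verdict rather than an error.

All metrics are linear or monotone under global dose scaling, which the
tests exploit.

## 5. Synthetic phantom

`make_phantom` builds a deterministic left-sided (mirrorable) thorax on a
2.5 mm isotropic grid (144 × 104 × 136 voxels, 360 × 260 × 340 mm field of
view):

- **body** — elliptic cylinder (semiaxes 150 × 80 mm) plus the breast bulge;
- **CTV-breast** (~824 cc) — the part of an ellipsoid lying **outside** the
  body cylinder's surface, so its posterior surface is curved like a
  residual breast on the chest wall rather than a flat cut;
- **nodal levels** — axillary levels I–IV plus interpectoral, grouped into
  CTVN (~89 cc) by the pipeline;
- **CTV-IMN** — a thin parasternal tube (~6 cc), deliberately the hardest
  structure (thin targets dominate sDSC and coverage failure modes);
- **OARs** — heart, both lungs, contralateral breast, esophagus, thyroid,
  humeral head.

The phantom emulates the *geometry and relative scale* of a locoregional
breast case — what drives border, surface, and dose-proximity behaviour. It
does not emulate image intensities, tissue heterogeneity, or anatomical
texture.

## 6. Observer simulator

An observer is generated by thresholding the reference structure's signed
Euclidean distance field against a smooth random field:
`occupied ⇔ signed_distance ≤ displacement_field`, where the field is white
noise blurred to a correlation length (default 20 mm), normalized to unit
variance, and scaled by `√(π/2) × sigma_mm` so that the **mean absolute
boundary displacement equals `sigma_mm`** (for a zero-mean Gaussian,
E|X| = σ√(2/π)). One field per observer is shared across that observer's
structures, emulating a systematic contouring tendency rather than voxel
speckle. `sigma_mm = 0` returns the reference exactly; a displaced level set
that vanishes keeps the deepest interior voxel (clinicians do not submit
empty structures). Signed distances are precomputed once per label, so large
cohorts are cheap.

Empirically (20 observers, σ = 3 mm) the measured mean absolute surface
displacement is ≈ 3.5 mm, and the cohort-mean sDSC at 3 mm tolerance
decreases strictly across σ ∈ {1, 2, 4, 8} mm.

## 7. Dose model

`synthetic_dose` produces an idealized *planned* dose for one field
technique, not a transport calculation:

1. **Aperture** — the PTV (intersected with the body) expanded isotropically
   by `aperture_factor (2.2) × penumbra_mm (6)`, then extended as a binary
   union of shifted copies **along the beam axis**, so the penumbra falls
   outside the target as in a planned field.
2. **Beam axis** — chest-wall-tangential oblique step `(±4, 1, 0)` voxels
   for `technique="tangential"` (opposed breast fields grazing the thoracic
   wall; sign follows laterality), `(0, 1, 0)` for `"ap_pa"` (opposed nodal
   fields); overridable via `beam_step_voxels`.
3. **Penumbra** — isotropic Gaussian blur of scale `penumbra_mm`, followed
   by an extra 1-D Gaussian along the beam axis making the penumbra
   `elongation (4)` times longer along the beam than across it (beam-edge
   penumbras are sharp, depth falloff is gentle).
4. **Midline border** (tangential only) — a sharp collimated field edge: the
   blurred field is multiplied by an erf profile of width `penumbra_mm`
   placed `midline_margin_mm (15)` beyond the sternal midline `x = 0` on the
   contralateral side. This is what keeps contralateral-breast dose low and
   makes the medial breast border dosimetrically consequential.
5. **Bath + support** — a uniform `bath_fraction (2%)` of prescription is
   added inside the body; dose is identically zero outside the body and
   bounded by `prescription × (1 + bath_fraction)`.

With `penumbra_mm = 0` the model reduces exactly to prescription inside the
PTV — the analytically testable limit.

The pipeline's locoregional plan uses **wide tangents**: one tangential
field on PTV-breast ∪ PTV-IMN plus an AP-PA field on the
axillary/supraclavicular PTVN, combined by voxelwise maximum. Treating the
IMN through the tangents (rather than an anterior nodal field reaching it at
full depth) is what keeps heart Dmean below ~1 Gy while covering the
parasternal chain. The model reproduces the clinically expected ordering —
moving the breast CTV's posterior-medial border toward the heart strictly
increases heart Dmean, because the enlarged target yields a superset
aperture and the blur kernel is nonnegative (pointwise dose monotonicity).

The dose model does **not** emulate scatter, heterogeneity corrections,
beam energy, or optimizer behaviour; it is a geometric surrogate whose
qualitative properties (coverage, proximity-driven OAR dose, field borders)
are the object of study.

## 8. Pipeline

`run_analysis(AnalysisConfig)` runs: phantom + observer simulation (or file
loading) → node grouping and PTV derivation per observer → consensus per
grouped label → five report tables:

1. **volumes** — per-observer volumes with min/max/range per structure;
2. **borders** — border extents (mm) and maximum pairwise differences (cm)
   for the breast (4 borders), CTVN (cranial/caudal), IMN (caudal);
3. **sdsc** — per observer/structure/tolerance against the configured
   reference (consensus by default), with recomputed mean/median rows;
4. **oar_dose** — OAR metric catalogue per plan (heart Dmean and V17Gy, lung
   V16Gy/V5Gy/Dmean, contralateral organs, esophagus, thyroid, humeral head,
   body V105%, ICRU volumes);
5. **coverage** — every plan cross-applied to every observer's structures:
   D98% verdicts plus the volume outside the PTV above 90% of prescription.

Reports are written as CSV (2-decimal floats) with full-precision JSON
mirrors and provenance metadata (config SHA-256 digest, seed, software
version). Everything is deterministic given the configuration.

## 9. Numerical choices, in brief

- exact `cKDTree` nearest neighbours for sDSC (no distance-map quantization);
- integer-count consensus threshold (no float ties);
- exact sorting for D98% (no histogram binning error);
- whole-voxel counting everywhere (direct oracles in the tests);
- centre-containment rasterization and centre-to-centre expansion — simple,
  exact to state, with a known ≤ half-voxel digitization bias;
- truncated (3.5σ) Gaussian kernels in the dose model, deterministic and
  platform-stable.

## 10. Limitations

- Voxel-centre digitization biases volumes and expansions by up to half a
  voxel at the surface; analytic comparisons hold to ~2% at 1 mm spacing
  for 20 mm-scale structures.
- The observer model perturbs a single reference; it does not model
  systematic inter-institutional protocol differences (e.g. different
  cranial field borders by policy), only smooth random boundary variation.
- The dose model is a geometric surrogate (see §7); absolute OAR doses are
  plausible in ordering and magnitude, not commissioning-grade.
- Masks are resampled nearest-neighbour and doses trilinearly; no oblique
  (non-axis-aligned) grids are supported.
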