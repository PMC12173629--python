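# rtcompare

Multi-observer comparison of radiotherapy target volumes and dosimetric
evaluation of the resulting plans, on voxel grids.

When several clinicians (or automated models) delineate the same target —
here the setting of locoregional breast radiotherapy — their contours
disagree. `rtcompare` quantifies that disagreement and propagates it into
dose: it measures volumes and border positions per observer, builds a
consensus ("mean") structure, scores every observer against a reference with
the surface dice similarity coefficient (sDSC), plans an idealized dose on
each candidate target, and cross-applies every plan to every observer's
structures to see which coverage criteria would still hold.

Because real patient CTs and clinical contours cannot ship with a software
package, `rtcompare` includes a deterministic synthetic thorax phantom
(breast, axillary/supraclavicular node levels, internal mammary chain, and
seven organs at risk) plus an observer simulator that perturbs the reference
contours with smooth, spatially correlated boundary noise of a chosen mean
absolute displacement. Every pipeline stage also accepts real data through
NIfTI masks/doses and DICOM RT Structure Sets.

## Components

| module | contents |
| --- | --- |
| `rtcompare.grid` | `VoxelGrid`: axis-aligned lattice, voxel-center world coordinates |
| `rtcompare.mask` | `StructureMask`/`StructureSet`, contour rasterization, volumes, CTV→PTV expansion, boolean ops, border extents and inter-observer border differences |
| `rtcompare.consensus` | mean (consensus) structure: voxel occupied when the observer average is ≥ 0.5 |
| `rtcompare.surface` | voxel-face surface extraction, sDSC, per-cohort sDSC tables |
| `rtcompare.dosimetry` | DVH engine: Dmean, VxGy, D98%, ICRU treated/irradiated volumes, volume outside the PTV above 90% of prescription, coverage verdicts |
| `rtcompare.phantom` | synthetic thorax phantom, observer simulator, idealized tangential / AP-PA dose model |
| `rtcompare.pipeline` | `AnalysisConfig` → `run_analysis` → `MetricsReport` (five report tables, written as CSV + JSON) |
| `rtcompare.io` | NIfTI masks and doses, DICOM RT Structure Set reading |
| `rtcompare.cli` | `rtcompare simulate / analyze / sdsc / dvh` |

## Worked example

Simulate five observers contouring the phantom breast CTV with 3 mm mean
boundary noise, build their consensus, and evaluate a tangential plan on it:

```python
from rtcompare import (PhantomSpec, make_phantom, ObserverSimulator, mean_structure,
                       surface_dice, expand_mask, intersection, synthetic_dose, d_mean,
                       d_percent_coverage)

reference = make_phantom(PhantomSpec())
sim = ObserverSimulator(reference, labels=("CTV-breast",))
cohort = sim.cohort(5, sigma_mm=3.0, seed=42)

ref = reference["CTV-breast"]
print(f"reference CTV-breast volume: {ref.volume_cc():.1f} cc")
for obs in cohort:
    m = obs["CTV-breast"]
    s = surface_dice(m, ref, 3.0)
    print(f"{obs.observer_id}: volume {m.volume_cc():.1f} cc, sDSC@3mm {s.value:.3f}")

consensus = mean_structure([o["CTV-breast"] for o in cohort])
print(f"consensus volume: {consensus.mask.volume_cc():.1f} cc")

body = reference["body"]
ptv = intersection([expand_mask(consensus.mask, 5.0, "PTV"), body], "PTV")
dose = synthetic_dose(ptv, body, technique="tangential")
print(f"PTV D98%: {d_percent_coverage(dose, ptv):.1f} % of prescription")
print(f"heart Dmean: {d_mean(dose, reference['heart']):.2f} Gy")
```

Output (deterministic):

```
reference CTV-breast volume: 824.0 cc
observer01: volume 859.7 cc, sDSC@3mm 0.742
observer02: volume 751.4 cc, sDSC@3mm 0.753
observer03: volume 758.9 cc, sDSC@3mm 0.700
observer04: volume 864.2 cc, sDSC@3mm 0.842
observer05: volume 732.6 cc, sDSC@3mm 0.696
consensus volume: 799.2 cc
PTV D98%: 100.9 % of prescription
heart Dmean: 0.80 Gy
```

The full pipeline (all targets, node grouping, borders, sDSC tables, OAR
dosimetry, plan cross-application) runs from one config:

```bash
rtcompare analyze --out reports/ --seed 0
```

which writes `volumes.csv`, `borders.csv`, `sdsc.csv`, `oar_dose.csv`,
`coverage.csv` (plus JSON mirrors and provenance metadata) under `reports/`.
`rtcompare simulate --out cohort/` exports the phantom cohort as NIfTI for
use with external tools, and `rtcompare sdsc a.nii.gz b.nii.gz` /
`rtcompare dvh dose.nii.gz mask.nii.gz` compute single-pair metrics.

## Reproducing results

Everything is deterministic given a seed.

```bash
pip install --no-build-isolation -e .[test]
pytest -q                                             # full test suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` recomputes the two analytic boundary values of the
sDSC from scratch — a structure against an identical copy of itself
(exactly 1 at 3 mm and 5 mm tolerance) and two structures everywhere farther
apart than the tolerance (exactly 0) — and writes them as JSON. The seed
jitters the sphere positions on the grid; the values are exact invariants
and do not change.

See `docs/methods.md` for the model definitions, parameter choices, and
numerical conventions.
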