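"""End-to-end multi-observer analysis: the four report families.

Given a cohort of observers' target delineations (synthetic or from files),
a reference policy and a dose model, :func:`run_analysis` produces:

* ``volumes``  — per-observer structure volumes with min/max/range,
* ``borders``  — border extents and maximal pairwise border differences,
* ``sdsc``     — surface dice against the reference, with mean/median rows,
* ``oar_dose`` — organ-at-risk dose metrics per plan,
* ``coverage`` — cross-application of every plan to every observer's
  structures: D98% guideline verdicts and the irradiated volume outside the
  PTV.

Everything is deterministic given the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import mean_structure
from .dosimetry import (
    DEFAULT_COVERAGE_CRITERIA,
    DoseGrid,
    coverage_report,
    d_mean,
    d_percent_coverage,
    icru_volumes,
    irradiated_outside_ptv,
    v_dose,
)
from .io import read_mask_volume
from .mask import (
    StructureMask,
    StructureSet,
    border_difference_table,
    border_extents,
    expand_mask,
    intersection,
    resample_mask,
    union,
)
from .phantom import NODE_LABELS, ObserverSimulator, PhantomSpec, make_phantom, synthetic_dose
from .surface import sdsc_table

__all__ = ["AnalysisConfig", "MetricsReport", "run_analysis", "summarize_volumes"]

logger = logging.getLogger(__name__)

#: The grouped structures compared between observers.
ANALYSIS_LABELS = ("CTV-breast", "CTVN", "CTV-IMN")

#: Which borders are compared for which structure (breast: all four;
#: nodal volume: cranial and caudal; internal mammary chain: caudal).
BORDER_PLAN = {
    "CTV-breast": ("cranial", "caudal", "medial", "lateral"),
    "CTVN": ("cranial", "caudal"),
    "CTV-IMN": ("caudal",),
}

#: Organ-at-risk metric catalogue: (structure, metric name, callable args).
OAR_METRICS: tuple[tuple[str, str, dict], ...] = (
    ("heart", "Dmean_Gy", {"kind": "dmean"}),
    ("heart", "V17Gy_pct", {"kind": "v", "threshold": 17.0, "output": "percent"}),
    ("lung-ipsilateral", "V16Gy_pct", {"kind": "v", "threshold": 16.0, "output": "percent"}),
    ("lung-ipsilateral", "Dmean_Gy", {"kind": "dmean"}),
    ("lung-ipsilateral", "V5Gy_pct", {"kind": "v", "threshold": 5.0, "output": "percent"}),
    ("lung-contralateral", "Dmean_Gy", {"kind": "dmean"}),
    ("breast-contralateral", "Dmean_Gy", {"kind": "dmean"}),
    ("esophagus", "V9Gy_cc", {"kind": "v", "threshold": 9.0, "output": "cc"}),
    ("esophagus", "V18Gy_cc", {"kind": "v", "threshold": 18.0, "output": "cc"}),
    ("esophagus", "Dmean_Gy", {"kind": "dmean"}),
    ("thyroid", "Dmean_Gy", {"kind": "dmean"}),
    ("body", "V105pct_cc", {"kind": "v", "threshold": "105%", "output": "cc"}),
    ("humeral-head", "Dmean_Gy", {"kind": "dmean"}),
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to reproduce one analysis run."""

    mode: str = "synthetic"  # 'synthetic' | 'files'
    seed: int = 0
    n_observers: int = 10
    sigma_mm: float = 3.0
    correlation_mm: float = 20.0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    observer_files: tuple = ()  # mode='files': ({'observer_id':…, 'masks':{label: path}}, …)
    reference_policy: str = "consensus"  # 'consensus' or an observer id
    tolerances_mm: tuple[float, ...] = (3.0, 5.0)
    prescription_gy: float = 40.05
    n_fractions: int = 15
    margin_mm: float = 5.0
    penumbra_mm: float = 6.0
    bath_fraction: float = 0.02
    elongation: float = 4.0
    coverage_criteria: dict = field(
        default_factory=lambda: dict(DEFAULT_COVERAGE_CRITERIA)
    )
    plan_sources: tuple[str, ...] = ("consensus", "observer01", "observer02")
    crop_ptv_to_body: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if any(t <= 0 for t in self.tolerances_mm):
            raise ValueError("tolerances must be > 0")
        if self.mode == "synthetic" and self.n_observers < 2:
            raise ValueError("comparison reports need at least 2 observers")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "phantom" in raw:
            raw["phantom"] = PhantomSpec(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["phantom"].items()
            })
        for key in ("tolerances_mm", "plan_sources", "observer_files"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class MetricsReport:
    """The four report tables plus provenance metadata."""

    volumes: pd.DataFrame
    borders: pd.DataFrame
    sdsc: pd.DataFrame
    oar_dose: pd.DataFrame
    coverage: pd.DataFrame
    metadata: dict

    _TABLES = ("volumes", "borders", "sdsc", "oar_dose", "coverage")

    def write(self, outdir: str | Path) -> None:
        """One CSV per table (floats at 2 decimals), a JSON mirror at full
        precision, and the provenance metadata."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            df: pd.DataFrame = getattr(self, name)
            df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.2f")
            df.to_json(outdir / f"{name}.json", orient="records", indent=1)
        (outdir / "metadata.json").write_text(json.dumps(self.metadata, indent=1))


def summarize_volumes(
    sets: list[StructureSet], labels: tuple[str, ...]
) -> pd.DataFrame:
    """Per-observer volumes in cc with min/max/range summary rows per label."""
    if not sets:
        raise ValueError("need at least one observer")
    rows = []
    for lb in labels:
        vals = []
        for s in sets:
            if lb not in s:
                continue
            v = s[lb].volume_cc()
            vals.append(v)
            rows.append({"observer": s.observer_id, "structure": lb, "volume_cc": v})
        if vals:
            arr = np.asarray(vals)
            for stat, v in (("min", arr.min()), ("max", arr.max()),
                            ("range", arr.max() - arr.min())):
                rows.append({"observer": stat, "structure": lb, "volume_cc": float(v)})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# internal stages
# ----------------------------------------------------------------------

def _load_file_observers(config: AnalysisConfig) -> tuple[StructureSet, list[StructureSet]]:
    if not config.observer_files:
        raise ValueError("mode='files' requires observer_files entries")
    sets = []
    ref_grid = None
    for entry in config.observer_files:
        s = StructureSet(entry["observer_id"])
        for label, path in entry["masks"].items():
            m = read_mask_volume(path, label=label)
            if ref_grid is None:
                ref_grid = m.grid
            s.add(resample_mask(m, ref_grid))
        sets.append(s)
    reference = sets[0]
    if "body" not in reference:
        raise ValueError("the first observer must provide a 'body' structure")
    return reference, sets


def _derive_observer(s: StructureSet, body: StructureMask, config: AnalysisConfig) -> StructureSet:
    """Group node levels into CTVN and expand CTVs into PTVs."""
    out = StructureSet(s.observer_id)
    for lb in s.labels():
        out.add(s[lb].copy())
    nodes = [s[lb] for lb in NODE_LABELS if lb in s]
    if nodes and "CTVN" not in out:
        out.add(union(nodes, label="CTVN"))
    for ctv_label in ANALYSIS_LABELS:
        if ctv_label not in out:
            continue
        ptv_label = "PTV" + ctv_label.removeprefix("CTV").lstrip("-")
        ptv_label = {"CTV-breast": "PTV-breast", "CTVN": "PTVN",
                     "CTV-IMN": "PTV-IMN"}[ctv_label]
        ptv = expand_mask(out[ctv_label], config.margin_mm, label=ptv_label)
        if config.crop_ptv_to_body:
            ptv = intersection([ptv, body], label=ptv_label)
        out.add(ptv)
    if "CTV-breast" in out and "CTVN" in out:
        out.add(union([out["CTV-breast"], out["CTVN"]], label="CTV-breast+CTVN"))
        out.add(union([out["PTV-breast"], out["PTVN"]], label="PTV-breast+PTVN"))
    ptvs = [out[lb] for lb in ("PTV-breast", "PTVN", "PTV-IMN") if lb in out]
    if ptvs:
        out.add(union(ptvs, label="PTV-total"))
    ctvs = [out[lb] for lb in ANALYSIS_LABELS if lb in out]
    if ctvs:
        out.add(union(ctvs, label="CTV-total"))
    return out


def _build_plan(source: StructureSet, body: StructureMask, config: AnalysisConfig) -> DoseGrid:
    """Locoregional plan: wide tangential fields on the breast + parasternal
    (IMN) PTVs combined with AP-PA fields on the axillary/supraclavicular
    nodal PTV (voxelwise maximum)."""
    laterality = config.phantom.laterality if config.mode == "synthetic" else "left"
    kwargs = dict(
        prescription_gy=config.prescription_gy,
        n_fractions=config.n_fractions,
        penumbra_mm=config.penumbra_mm,
        bath_fraction=config.bath_fraction,
        elongation=config.elongation,
        laterality=laterality,
    )
    components = []
    tangent = [source[lb] for lb in ("PTV-breast", "PTV-IMN") if lb in source]
    if tangent:
        components.append(
            synthetic_dose(
                union(tangent, label="PTV-tangential"), body,
                technique="tangential", **kwargs,
            )
        )
    if "PTVN" in source:
        components.append(
            synthetic_dose(source["PTVN"], body, technique="ap_pa", **kwargs)
        )
    if not components:
        raise ValueError(f"plan source {source.observer_id!r} has no PTV structures")
    dose = components[0].dose.copy()
    for c in components[1:]:
        np.maximum(dose, c.dose, out=dose)
    return DoseGrid(body.grid, dose, config.prescription_gy, config.n_fractions)


def _borders_table(derived: list[StructureSet], laterality: str) -> pd.DataFrame:
    rows = []
    for lb, borders in BORDER_PLAN.items():
        present = [s for s in derived if lb in s]
        for s in present:
            ext = border_extents(s[lb], laterality).as_dict()
            for b in borders:
                rows.append({"structure": lb, "border": b,
                             "observer": s.observer_id, "value_mm": ext[b]})
        if len(present) >= 2:
            diffs = border_difference_table(present, lb, borders, laterality)
            for b, v in diffs.items():
                rows.append({"structure": lb, "border": b,
                             "observer": "max-pairwise-difference-cm", "value_mm": v})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# the orchestrator
# ----------------------------------------------------------------------

def run_analysis(config: AnalysisConfig) -> MetricsReport:
    """Run the full comparison and dosimetric evaluation.

    Stage failures abort with the stage and offending structure named in the
    raised exception / log.  Deterministic given ``config`` (which includes
    the seed).
    """
    try:
        if config.mode == "synthetic":
            reference = make_phantom(config.phantom)
            sim = ObserverSimulator(reference)
            observers = sim.cohort(
                config.n_observers, config.sigma_mm, config.correlation_mm, config.seed
            )
            laterality = config.phantom.laterality
        else:
            reference, observers = _load_file_observers(config)
            laterality = "left"
        body = reference["body"]
    except Exception:
        logger.exception("stage 'inputs' failed")
        raise

    derived = [_derive_observer(s, body, config) for s in observers]

    # consensus (mean structure) per grouped label, built once and reused
    consensus_set = StructureSet("consensus")
    grouped_for_consensus = {}
    for lb in ANALYSIS_LABELS:
        masks = [s[lb] for s in derived if lb in s]
        if not masks:
            logger.warning("no observer delineated %r; label skipped", lb)
            continue
        cons = mean_structure(masks, label=lb)
        consensus_set.add(cons.mask.copy(label=lb))
        grouped_for_consensus[lb] = cons
    derived_consensus = _derive_observer(consensus_set, body, config)

    # reference for the surface-dice table
    if config.reference_policy == "consensus":
        reference_masks = {lb: derived_consensus[lb] for lb in ANALYSIS_LABELS
                           if lb in derived_consensus}
    else:
        named = {s.observer_id: s for s in derived}
        if config.reference_policy not in named:
            raise ValueError(f"reference observer {config.reference_policy!r} not found")
        ref_set = named[config.reference_policy]
        reference_masks = {lb: ref_set[lb] for lb in ANALYSIS_LABELS if lb in ref_set}

    volumes = summarize_volumes(
        derived + [derived_consensus], ANALYSIS_LABELS + ("CTV-total",)
    )
    borders = _borders_table(derived, laterality)
    sdsc = sdsc_table(derived, reference_masks,
                      [lb for lb in ANALYSIS_LABELS if lb in reference_masks],
                      config.tolerances_mm)

    # plans from the configured sources, each applied to every observer
    sources = {s.observer_id: s for s in derived}
    sources["consensus"] = derived_consensus
    plans: dict[str, DoseGrid] = {}
    for name in config.plan_sources:
        if name not in sources:
            raise ValueError(f"plan source {name!r} is not an observer or 'consensus'")
        plans[name] = _build_plan(sources[name], body, config)

    oar_rows = []
    for plan_name, dose in plans.items():
        for structure, metric, how in OAR_METRICS:
            mask = reference[structure] if structure in reference else None
            if mask is None:
                logger.warning("OAR %r missing; metric %s skipped", structure, metric)
                continue
            if how["kind"] == "dmean":
                val = d_mean(dose, mask)
            else:
                val = v_dose(dose, mask, how["threshold"], how["output"])
            oar_rows.append({"plan": plan_name, "structure": structure,
                             "metric": metric, "value": val})
        treated, irradiated = icru_volumes(dose, body)
        oar_rows.append({"plan": plan_name, "structure": "body",
                         "metric": "ICRU_treated_cc", "value": treated})
        oar_rows.append({"plan": plan_name, "structure": "body",
                         "metric": "ICRU_irradiated_cc", "value": irradiated})
    oar_dose = pd.DataFrame(oar_rows)

    # cross-application: every plan evaluated on every observer + consensus
    cov_rows = []
    eval_sets = derived + [derived_consensus]
    for plan_name, dose in plans.items():
        for s in eval_sets:
            structures = {lb: s[lb] for lb in config.coverage_criteria if lb in s}
            for v in coverage_report(dose, structures, config.coverage_criteria):
                cov_rows.append({
                    "plan": plan_name, "observer": s.observer_id,
                    "structure": v.structure, "metric": v.metric,
                    "threshold_pct": v.threshold_pct,
                    "achieved_pct": v.achieved_pct,
                    "passed": v.passed, "evaluable": v.evaluable,
                })
            if "PTV-total" in s:
                outside = irradiated_outside_ptv(dose, s["PTV-total"], body)
                cov_rows.append({
                    "plan": plan_name, "observer": s.observer_id,
                    "structure": "PTV-Body", "metric": "V90pct_outside_ptv_cc",
                    "threshold_pct": np.nan, "achieved_pct": outside,
                    "passed": None, "evaluable": True,
                })
    coverage = pd.DataFrame(cov_rows)

    metadata = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "software_version": __version__,
        "n_observers": len(observers),
        "reference_policy": config.reference_policy,
        "prescription_gy": config.prescription_gy,
        "n_fractions": config.n_fractions,
    }
    return MetricsReport(volumes, borders, sdsc, oar_dose, coverage, metadata)
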