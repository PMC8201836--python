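"""Plan evaluation against the clinical objective tables, mitigation
strategies, and cohort-level summaries.

Objectives: the CTV is prescribed D90% = 30 Gy with heterogeneity aims
V45Gy >= 50-55% and V60Gy >= 30%; each organ at risk carries a boost D2cm3
aim and a hard upper limit (bladder 23.75/27.5, rectum 17.0/19.45, sigmoid
19.5/21.65, bowel 17.0/19.45 Gy), equivalent to cumulative EQD2 limits of
80/65/70/65 Gy once a prior uniform 45 Gy EBRT course is added.

Coverage mitigation: a plan normalised to CTV D90% = 30 Gy underdoses the
2 mm and 5 mm setup-margin expansions; strategy A renormalises the plan
globally to the highest scale that violates no OAR hard limit, and strategy B
first re-optimises with the PTV2mm as an additional coverage structure and
then applies the same renormalisation.  Because every D-metric is exactly
linear in a global scale, the optimal scale has the closed form
``min over OARs of (hard limit / current D2cm3)``.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import DoseGrid, StructureMask, StructureSet
from .dvh import (
    DVHCurve,
    average_dvh,
    compute_dvh,
    voxel_dose_at_volume_cm3,
    voxel_dose_at_volume_pct,
    volume_pct_at_dose,
)
from .optimizer import OptimizationResult, OptimizerConfig, optimize
from .radiobiology import ALPHA_BETA_OAR, ALPHA_BETA_TARGET, PriorCourse, cumulative_eqd2
from .rods import RodSet, expand

__all__ = [
    "OARObjective",
    "PlanObjectives",
    "PlanReport",
    "CohortSummary",
    "load_objectives",
    "evaluate_plan",
    "mitigate_renormalize",
    "mitigate_reoptimize",
    "summarize_cohort",
]

_REL_TOL = 1e-9  # hard-limit comparisons are exact up to float round-off


@dataclass(frozen=True)
class OARObjective:
    aim_gy: float
    hard_gy: float
    cumulative_eqd2_gy: float | None = None

    def __post_init__(self) -> None:
        if self.hard_gy < self.aim_gy:
            raise ValueError(
                f"hard limit {self.hard_gy} Gy below the aim {self.aim_gy} Gy"
            )


@dataclass(frozen=True)
class PlanObjectives:
    """CTV aims plus per-OAR D2cm3 aim / hard-limit pairs (boost Gy)."""

    prescription_gy: float = 30.0
    n_fractions: int = 5
    ctv_d90_gy: float = 30.0
    ctv_v45_aim_pct: float = 50.0
    ctv_v60_aim_pct: float = 30.0
    oars: dict[str, OARObjective] = field(
        default_factory=lambda: {
            "bladder": OARObjective(23.75, 27.5, 80.0),
            "rectum": OARObjective(17.0, 19.45, 65.0),
            "sigmoid": OARObjective(19.5, 21.65, 70.0),
            "bowel": OARObjective(17.0, 19.45, 65.0),
        }
    )
    prior: PriorCourse = field(default_factory=PriorCourse)

    def hard_limits(self) -> dict[str, float]:
        return {name: o.hard_gy for name, o in self.oars.items()}


def load_objectives(path: str | Path | None = None) -> PlanObjectives:
    """Load objectives from a YAML constraints file (packaged defaults if None)."""
    if path is None:
        ref = importlib.resources.files("rodplan").joinpath("data/constraints.yaml")
        text = ref.read_text()
    else:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"objectives file not found: {path}")
        text = path.read_text()
    raw = yaml.safe_load(text)
    oars = {
        name: OARObjective(
            aim_gy=float(o["aim_gy"]),
            hard_gy=float(o["hard_gy"]),
            cumulative_eqd2_gy=float(o["cumulative_eqd2_gy"])
            if "cumulative_eqd2_gy" in o
            else None,
        )
        for name, o in raw["oars"].items()
    }
    prior = PriorCourse(
        total_gy=float(raw["prior_course"]["total_gy"]),
        n_fractions=int(raw["prior_course"]["n_fractions"]),
    )
    return PlanObjectives(
        prescription_gy=float(raw["prescription_gy"]),
        n_fractions=int(raw["n_fractions"]),
        ctv_d90_gy=float(raw["ctv"]["d90_gy"]),
        ctv_v45_aim_pct=float(raw["ctv"]["v45_aim_pct"]),
        ctv_v60_aim_pct=float(raw["ctv"]["v60_aim_pct"]),
        oars=oars,
        prior=prior,
    )


@dataclass
class PlanReport:
    """Scalar metrics (physical and cumulative EQD2) plus pass/fail flags."""

    strategy: str
    normalization_scale: float
    metrics: dict[str, dict[str, float]]  # structure -> metric name -> value
    aim_failures: list[str]
    hard_violations: list[str]
    objectives: PlanObjectives
    dvh_curves: dict[str, DVHCurve] = field(default_factory=dict)

    @property
    def passed_hard_limits(self) -> bool:
        return not self.hard_violations

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "normalization_scale": self.normalization_scale,
            "metrics": {s: dict(m) for s, m in self.metrics.items()},
            "aim_failures": list(self.aim_failures),
            "hard_violations": list(self.hard_violations),
        }


def _ptv_expansions(structures: StructureSet) -> StructureSet:
    """Return a structure set that also contains PTV2mm and PTV5mm."""
    out = StructureSet(structures.grid, dict(structures.masks))
    ctv = structures["CTV"]
    for margin, name in ((2.0, "PTV2mm"), (5.0, "PTV5mm")):
        if name not in out:
            ptv = expand(ctv, margin)
            out.add(StructureMask(name, structures.grid, ptv.data))
    return out


def evaluate_plan(
    dose: DoseGrid,
    structures: StructureSet,
    objectives: PlanObjectives | None = None,
    prior: PriorCourse | None = None,
    strategy: str = "",
    normalization_scale: float = 1.0,
    keep_dvh: bool = False,
) -> PlanReport:
    """Compute all plan metrics and flag aim and hard-limit violations.

    Metrics: CTV D90/V45/V60, PTV2mm and PTV5mm D90 (expansions generated on
    the fly when absent), and each OAR's D2cm3, all reported both as physical
    boost dose and as cumulative EQD2 (alpha/beta = 10 for target structures,
    3 for OARs, summed with the prior EBRT course).  Scalar D-metrics use
    exact voxel quantiles; DVH curves (0.02 Gy bins) are attached on request.
    """
    objectives = objectives if objectives is not None else PlanObjectives()
    prior = prior if prior is not None else objectives.prior
    structures.require(["CTV"] + list(objectives.oars))
    full = _ptv_expansions(structures)
    n_fx = objectives.n_fractions

    metrics: dict[str, dict[str, float]] = {}
    aim_failures: list[str] = []
    hard_violations: list[str] = []
    curves: dict[str, DVHCurve] = {}

    for name in ("CTV", "PTV2mm", "PTV5mm"):
        mask = full[name]
        dvh = compute_dvh(dose, mask)
        d90 = voxel_dose_at_volume_pct(dose, mask, 90.0)
        entry = {
            "volume_cm3": mask.volume_cm3,
            "D90_gy": d90,
            "D90_eqd2_cum_gy": cumulative_eqd2(d90, n_fx, ALPHA_BETA_TARGET, prior),
            "V45_pct": volume_pct_at_dose(dvh, 45.0),
            "V60_pct": volume_pct_at_dose(dvh, 60.0),
        }
        metrics[name] = entry
        if keep_dvh:
            curves[name] = dvh

    ctv = metrics["CTV"]
    if ctv["D90_gy"] < objectives.ctv_d90_gy * (1 - 1e-6):
        aim_failures.append(
            f"CTV D90 {ctv['D90_gy']:.2f} Gy < {objectives.ctv_d90_gy} Gy"
        )
    if ctv["V45_pct"] < objectives.ctv_v45_aim_pct:
        aim_failures.append(
            f"CTV V45 {ctv['V45_pct']:.1f}% < {objectives.ctv_v45_aim_pct}%"
        )
    if ctv["V60_pct"] < objectives.ctv_v60_aim_pct:
        aim_failures.append(
            f"CTV V60 {ctv['V60_pct']:.1f}% < {objectives.ctv_v60_aim_pct}%"
        )

    for name, obj in objectives.oars.items():
        mask = structures[name]
        vol = mask.volume_cm3
        v_query = min(2.0, vol)
        d2 = voxel_dose_at_volume_cm3(dose, mask, v_query)
        entry = {
            "volume_cm3": vol,
            "D2cm3_gy": d2,
            "D2cm3_eqd2_cum_gy": cumulative_eqd2(d2, n_fx, ALPHA_BETA_OAR, prior),
        }
        metrics[name] = entry
        if keep_dvh:
            curves[name] = compute_dvh(dose, mask)
        if d2 > obj.hard_gy * (1 + _REL_TOL):
            hard_violations.append(
                f"{name} D2cm3 {d2:.3f} Gy > hard limit {obj.hard_gy} Gy"
            )
        elif d2 > obj.aim_gy * (1 + _REL_TOL):
            aim_failures.append(
                f"{name} D2cm3 {d2:.3f} Gy > aim {obj.aim_gy} Gy"
            )

    return PlanReport(
        strategy=strategy,
        normalization_scale=normalization_scale,
        metrics=metrics,
        aim_failures=aim_failures,
        hard_violations=hard_violations,
        objectives=objectives,
        dvh_curves=curves,
    )


def mitigate_renormalize(
    dose: DoseGrid,
    structures: StructureSet,
    objectives: PlanObjectives | None = None,
    target_structure: str = "PTV2mm",
    max_scale: float = 10.0,
) -> tuple[DoseGrid, float]:
    """Globally rescale the plan to the highest OAR-safe level (strategy A).

    The optimal scale is the closed form ``s* = min over OARs of
    (hard limit / current D2cm3)``: every D2cm3 is exactly linear in a global
    scale, so after scaling the binding OAR sits exactly at its hard limit
    and no OAR exceeds its own.  If no OAR receives any dose the scale is
    capped at ``max_scale`` with a warning.  Returns the scaled dose and s*.
    """
    objectives = objectives if objectives is not None else PlanObjectives()
    full = _ptv_expansions(structures)
    full.require([target_structure])
    scales = []
    for name, obj in objectives.oars.items():
        mask = structures[name]
        d2 = voxel_dose_at_volume_cm3(dose, mask, min(2.0, mask.volume_cm3))
        if d2 > 0:
            scales.append(obj.hard_gy / d2)
    if not scales:
        warnings.warn(
            f"no OAR receives dose; mitigation scale capped at {max_scale}",
            stacklevel=2,
        )
        s_star = max_scale
    else:
        s_star = min(scales)
    return dose.scaled(s_star), float(s_star)


def mitigate_reoptimize(
    structures: StructureSet,
    rods: RodSet,
    valley: StructureMask | None,
    config: OptimizerConfig,
    objectives: PlanObjectives | None = None,
    target_structure: str = "PTV2mm",
) -> tuple[PlanReport, DoseGrid, OptimizationResult]:
    """Re-optimise with a PTV coverage objective, then renormalise (strategy B).

    Runs the surrogate optimizer with ``target_structure`` added as a
    coverage structure at the prescription level, then applies
    :func:`mitigate_renormalize`.  The report is labeled
    ``"<strategy> B"``.
    """
    objectives = objectives if objectives is not None else PlanObjectives()
    full = _ptv_expansions(structures)
    result = optimize(full, rods, valley, config.with_(ptv_coverage=target_structure))
    mitigated, scale = mitigate_renormalize(
        result.dose, full, objectives, target_structure
    )
    report = evaluate_plan(
        mitigated,
        full,
        objectives,
        strategy=f"{config.strategy} B",
        normalization_scale=scale,
    )
    return report, mitigated, result


@dataclass
class CohortSummary:
    """Per-metric mean, sample SD and [min, max] across a cohort of plans."""

    n_plans: int
    stats: dict[str, dict[str, dict[str, float]]]  # structure -> metric -> stats

    def table(self) -> str:
        """Human-readable 'mean +/- SD [min, max]' table."""
        lines = [f"Cohort summary over {self.n_plans} plans"]
        for structure, per_metric in self.stats.items():
            for metric, s in per_metric.items():
                lines.append(
                    f"  {structure:8s} {metric:20s} "
                    f"{s['mean']:7.2f} +/- {s['sd']:5.2f} "
                    f"[{s['min']:.2f}, {s['max']:.2f}]"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"n_plans": self.n_plans, "stats": self.stats}


def summarize_cohort(reports: list[PlanReport]) -> CohortSummary:
    """Mean +/- sample SD and range of every metric across >= 2 plan reports."""
    if len(reports) < 2:
        raise ValueError("cohort summary requires at least two plan reports")
    ref = reports[0].objectives
    if any(r.objectives != ref for r in reports[1:]):
        raise ValueError("plan reports carry heterogeneous objectives")
    stats: dict[str, dict[str, dict[str, float]]] = {}
    for structure in reports[0].metrics:
        stats[structure] = {}
        for metric in reports[0].metrics[structure]:
            values = np.array([r.metrics[structure][metric] for r in reports])
            stats[structure][metric] = {
                "mean": float(values.mean()),
                "sd": float(values.std(ddof=1)),
                "min": float(values.min()),
                "max": float(values.max()),
            }
    return CohortSummary(n_plans=len(reports), stats=stats)


def average_structure_dvh(
    reports: list[PlanReport], structure: str
):
    """Average DVH (with SD bands) of one structure across reports that kept curves."""
    curves = [r.dvh_curves[structure] for r in reports if structure in r.dvh_curves]
    return average_dvh(curves)
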