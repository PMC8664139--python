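"""The automatic planning algorithm: isoeffect probing plus condition loop.

The controller runs in two steps.

**First step — per-case isoconstraint determination.**  The initial template
carries a deliberately unattainable serial isoconstraint on zRectum, so the
first optimization halts with that goal unattainable and reports the
isoeffect ``e0`` the metric actually reached.  The isoconstraint is then set
to ``0.9 · e0``, optimization is rerun to completion, and the isoconstraint
is finally fixed at the achieved isoeffect ``e1`` (a fixed point).  At the
same time the two bladder serial isoconstraints are set to their achieved
isoeffects reduced by 40%.  This tailors the OAR constraints to what each
case's geometry can support.

**Second step — condition loop.**  Optimization is repeated, and after each
pass four dose-index conditions are checked on the (un-normalized)
optimizer output:

1. PTV1: 93% ≤ V_78Gy ≤ 97%
2. Patient (body): D_2% ≤ 8170 cGy — checked only once condition 1 holds
3. PTV2: 93% ≤ V_72Gy ≤ 97%
4. Urethra: D_1% ≤ 8100 cGy

If a condition fails, one subroutine adjusts the template (one subroutine
per iteration, for the first failed condition): I and III escalate the
target-objective weights of PTV1/CTV resp. PTV2 (×2 per call, caps 500 for
underdose-DVH and 1000 for target-penalty weights) and, once all caps are
reached, loosen the competing OAR parameters; II and IV double the relevant
maximum-dose weights (cap 1000) to push hotspots down.  Over-coverage
(V above the 97% band) is handled by scaling the same target weights down
one step.  Every iteration is recorded in an audit trail.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

from .costs import CostFunction
from .dvh import normalize_plan, plan_indices
from .engine import DoseDistribution, OptimizeResult, SurrogateEngine
from .template import CAP_PENALTY, CAP_UNDERDOSE, PlanTemplate

__all__ = [
    "ConditionSet",
    "ConditionFailure",
    "ControllerConfig",
    "IterationRecord",
    "AuditTrail",
    "AutoplanError",
    "AutoplanResult",
    "first_step",
    "evaluate_conditions",
    "subroutine_I",
    "subroutine_II",
    "subroutine_III",
    "subroutine_IV",
    "overcoverage_step",
    "run_autoplan",
]


class AutoplanError(RuntimeError):
    """Controller-level failure (misconfigured template, missing index...)."""


@dataclass(frozen=True)
class ConditionSet:
    """The four termination conditions on the dose indices."""

    c1_low: float = 93.0  # % — PTV1 V_78Gy lower bound
    c1_high: float = 97.0
    c2_max_cgy: float = 8170.0  # body D_2%
    c3_low: float = 93.0  # % — PTV2 V_72Gy lower bound
    c3_high: float = 97.0
    c4_max_cgy: float = 8100.0  # urethra D_1%


@dataclass(frozen=True)
class ConditionFailure:
    condition: str  # "c1".."c4"
    direction: str  # "low" | "high"
    value: float
    bound: float


#: index-report keys consumed by the condition checker
CONDITION_KEYS = {
    "c1": "PTV1_V78Gy_pct",
    "c2": "body_D2pct_cGy",
    "c3": "PTV2_V72Gy_pct",
    "c4": "urethra_D1pct_cGy",
}


def evaluate_conditions(
    indices: Mapping[str, float], conditions: ConditionSet | None = None
) -> list[ConditionFailure]:
    """Failures in order c1, c2, c3, c4; c2 is suppressed until c1 passes."""
    cond = conditions or ConditionSet()
    for key in CONDITION_KEYS.values():
        if key not in indices:
            raise AutoplanError(f"missing dose index {key!r} for condition evaluation")
    failures: list[ConditionFailure] = []
    v1 = float(indices[CONDITION_KEYS["c1"]])
    c1_ok = cond.c1_low <= v1 <= cond.c1_high
    if v1 < cond.c1_low:
        failures.append(ConditionFailure("c1", "low", v1, cond.c1_low))
    elif v1 > cond.c1_high:
        failures.append(ConditionFailure("c1", "high", v1, cond.c1_high))
    if c1_ok:
        d2 = float(indices[CONDITION_KEYS["c2"]])
        if d2 > cond.c2_max_cgy:
            failures.append(ConditionFailure("c2", "high", d2, cond.c2_max_cgy))
    v2 = float(indices[CONDITION_KEYS["c3"]])
    if v2 < cond.c3_low:
        failures.append(ConditionFailure("c3", "low", v2, cond.c3_low))
    elif v2 > cond.c3_high:
        failures.append(ConditionFailure("c3", "high", v2, cond.c3_high))
    d1u = float(indices[CONDITION_KEYS["c4"]])
    if d1u > cond.c4_max_cgy:
        failures.append(ConditionFailure("c4", "high", d1u, cond.c4_max_cgy))
    return failures


@dataclass(frozen=True)
class ControllerConfig:
    """Step sizes and caps of the parameter-adjustment loop.

    The caps (500 for underdose-DVH weights, 1000 for target-penalty and
    maximum-dose weights) bound the weight escalation; the loosening steps
    apply once the caps are reached.  The probe and bladder reduction
    fractions belong to the first step.
    """

    cap_underdose: float = CAP_UNDERDOSE
    cap_penalty: float = CAP_PENALTY
    weight_escalation: float = 2.0
    weight_decrease_factor: float = 0.5
    weight_floor: float = 1.0
    loosen_iso_factor: float = 1.05
    shrink_step_mm: float = 2.0
    shrink_cap_mm: float = 40.0
    patient_qod_step_cgy: float = 1.0
    rectum_qod_step_cgy: float = 2.0
    oddvh_step_pp: float = 5.0
    overcoverage_factor: float = 0.8
    #: when a coverage condition's failure direction reverses (low <-> high),
    #: its weight-step factor contracts toward 1 (log-space bisection of the
    #: band): factor <- factor ** step_contraction, floored at min_step_factor
    step_contraction: float = 0.5
    min_step_factor: float = 1.05
    probe_reduction: float = 0.10
    bladder_reduction: float = 0.40
    max_outer_iterations: int = 30

    def __post_init__(self) -> None:
        if self.cap_underdose <= 0 or self.cap_penalty <= 0:
            raise AutoplanError("weight caps must be positive")
        if not (0 < self.probe_reduction < 1 and 0 < self.bladder_reduction < 1):
            raise AutoplanError("probe reduction fractions must lie in (0, 1)")
        if self.max_outer_iterations < 1:
            raise AutoplanError("max outer iterations must be >= 1")


# ---------------------------------------------------------------------------
# First step


def first_step(
    template: PlanTemplate,
    engine: SurrogateEngine,
    config: ControllerConfig | None = None,
) -> tuple[PlanTemplate, list[OptimizeResult]]:
    """Determine per-case zRectum and bladder isoconstraints by isoeffect
    feedback.  Returns the updated template and the two optimizer results.

    Raises :class:`AutoplanError` if the deliberate halt does not trigger
    (the template's probe isoconstraint is attainable — misconfigured).
    """
    cfg = config or ControllerConfig()
    probe = template.probe_function()
    bladder_serials = template.find(structure="bladder", kind="serial")
    if len(bladder_serials) != 2:
        raise AutoplanError("template must contain exactly two bladder serial functions")

    res0 = engine.optimize(template)
    if probe.id not in res0.unattainable:
        raise AutoplanError(
            "probe not triggered: the zRectum probe isoconstraint was attainable; "
            "the template is misconfigured for the first step"
        )
    e0 = res0.unattainable_isoeffects[probe.id]

    template = template.replace_function(
        probe, probe.with_(isoconstraint=(1.0 - cfg.probe_reduction) * e0)
    )
    probe = template.probe_function()

    res1 = engine.optimize(template)
    e1 = res1.isoeffects[probe.id]
    template = template.replace_function(probe, probe.with_(isoconstraint=e1))
    for cf in template.find(structure="bladder", kind="serial"):
        b = res1.isoeffects[cf.id]
        template = template.replace_function(
            cf, cf.with_(isoconstraint=(1.0 - cfg.bladder_reduction) * b)
        )
    return template, [res0, res1]


# ---------------------------------------------------------------------------
# Second-step subroutines


def _escalate_weight(cf: CostFunction, cap: float, factor: float) -> CostFunction:
    return cf.with_(weight=min(cap, cf.weight * factor))


def _target_escalation(
    template: PlanTemplate,
    structures: tuple[str, ...],
    cfg: ControllerConfig,
    factor: float | None = None,
) -> tuple[PlanTemplate, bool, dict]:
    """Phase A of subroutines I/III: scale target-objective weights up under
    their caps (x2 by default).  Returns (template, any_headroom, changes)."""
    factor = cfg.weight_escalation if factor is None else factor
    changes = {}
    any_headroom = False
    for cf in list(template.cost_functions):
        if cf.structure not in structures or not cf.is_target or cf.weight is None:
            continue
        cap = cfg.cap_underdose if cf.kind == "underdose_dvh" else cfg.cap_penalty
        if cf.weight < cap:
            any_headroom = True
            new = _escalate_weight(cf, cap, factor)
            changes[cf.id] = {"weight": [cf.weight, new.weight]}
            template = template.replace_function(cf, new)
    return template, any_headroom, changes


def subroutine_I(
    template: PlanTemplate,
    indices: Mapping[str, float],
    config: ControllerConfig | None = None,
    step_factor: float | None = None,
) -> tuple[PlanTemplate, dict]:
    """Raise PTV1 coverage: escalate PTV1/CTV target weights; once all are
    capped, loosen the bladder/patient parameters that compete with it."""
    cfg = config or ControllerConfig()
    v1 = float(indices[CONDITION_KEYS["c1"]])
    if v1 >= ConditionSet().c1_low:
        raise AutoplanError("subroutine I called while condition 1 is not failing low")
    template, headroom, changes = _target_escalation(template, ("PTV1", "CTV"), cfg, step_factor)
    if headroom:
        return template, {"subroutine": "I", "phase": "A", "changes": changes}
    for cf in template.find(structure="bladder", kind="serial"):
        new = cf.with_(
            weight=max(cfg.weight_floor, cf.weight * cfg.weight_decrease_factor),
            isoconstraint=cf.isoconstraint * cfg.loosen_iso_factor,
            shrink_margin_mm=min(cfg.shrink_cap_mm, cf.shrink_margin_mm + cfg.shrink_step_mm),
        )
        changes[cf.id] = {
            "weight": [cf.weight, new.weight],
            "isoconstraint": [cf.isoconstraint, new.isoconstraint],
            "shrink_margin_mm": [cf.shrink_margin_mm, new.shrink_margin_mm],
        }
        template = template.replace_function(cf, new)
    for cf in template.find(structure="patient", kind="quadratic_overdose"):
        new = cf.with_(isoconstraint=cf.isoconstraint + cfg.patient_qod_step_cgy)
        changes[cf.id] = {"isoconstraint": [cf.isoconstraint, new.isoconstraint]}
        template = template.replace_function(cf, new)
    return template, {"subroutine": "I", "phase": "B", "changes": changes}


def subroutine_II(
    template: PlanTemplate, indices: Mapping[str, float], config: ControllerConfig | None = None
) -> tuple[PlanTemplate, dict]:
    """Lower the body hotspot: double the patient maximum-dose weight."""
    cfg = config or ControllerConfig()
    d2 = float(indices[CONDITION_KEYS["c2"]])
    if d2 <= ConditionSet().c2_max_cgy:
        raise AutoplanError("subroutine II called while condition 2 passes")
    changes: dict = {}
    exhausted = True
    for cf in template.find(structure="patient", kind="maximum_dose"):
        if cf.weight < cfg.cap_penalty:
            exhausted = False
            new = _escalate_weight(cf, cfg.cap_penalty, cfg.weight_escalation)
            changes[cf.id] = {"weight": [cf.weight, new.weight]}
            template = template.replace_function(cf, new)
    return template, {"subroutine": "II", "exhausted": exhausted, "changes": changes}


def subroutine_III(
    template: PlanTemplate,
    indices: Mapping[str, float],
    config: ControllerConfig | None = None,
    step_factor: float | None = None,
) -> tuple[PlanTemplate, dict]:
    """Raise PTV2 coverage: escalate PTV2 target weights; once capped,
    loosen the zRectum/rectum-side constraints that compete with it."""
    cfg = config or ControllerConfig()
    v2 = float(indices[CONDITION_KEYS["c3"]])
    if v2 >= ConditionSet().c3_low:
        raise AutoplanError("subroutine III called while condition 3 is not failing low")
    template, headroom, changes = _target_escalation(template, ("PTV2",), cfg, step_factor)
    if headroom:
        return template, {"subroutine": "III", "phase": "A", "changes": changes}
    for cf in template.find(structure="zRectum", kind="serial"):
        new = cf.with_(
            isoconstraint=cf.isoconstraint * cfg.loosen_iso_factor,
            shrink_margin_mm=min(cfg.shrink_cap_mm, cf.shrink_margin_mm + cfg.shrink_step_mm),
        )
        changes[cf.id] = {
            "isoconstraint": [cf.isoconstraint, new.isoconstraint],
            "shrink_margin_mm": [cf.shrink_margin_mm, new.shrink_margin_mm],
        }
        template = template.replace_function(cf, new)
    for cf in template.find(structure="zRectum", kind="quadratic_overdose"):
        new = cf.with_(
            isoconstraint=cf.isoconstraint + cfg.rectum_qod_step_cgy,
            shrink_margin_mm=min(cfg.shrink_cap_mm, cf.shrink_margin_mm + cfg.shrink_step_mm),
        )
        changes[cf.id] = {
            "isoconstraint": [cf.isoconstraint, new.isoconstraint],
            "shrink_margin_mm": [cf.shrink_margin_mm, new.shrink_margin_mm],
        }
        template = template.replace_function(cf, new)
    for cf in template.find(structure="PTV2", kind="overdose_dvh"):
        new = cf.with_(isoconstraint=min(100.0, cf.isoconstraint + cfg.oddvh_step_pp))
        changes[cf.id] = {"isoconstraint": [cf.isoconstraint, new.isoconstraint]}
        template = template.replace_function(cf, new)
    return template, {"subroutine": "III", "phase": "B", "changes": changes}


def subroutine_IV(
    template: PlanTemplate, indices: Mapping[str, float], config: ControllerConfig | None = None
) -> tuple[PlanTemplate, dict]:
    """Lower the urethral hotspot: double the urethra maximum-dose weight."""
    cfg = config or ControllerConfig()
    d1 = float(indices[CONDITION_KEYS["c4"]])
    if d1 <= ConditionSet().c4_max_cgy:
        raise AutoplanError("subroutine IV called while condition 4 passes")
    changes: dict = {}
    exhausted = True
    for cf in template.find(structure="urethra", kind="maximum_dose"):
        if cf.weight < cfg.cap_penalty:
            exhausted = False
            new = _escalate_weight(cf, cfg.cap_penalty, cfg.weight_escalation)
            changes[cf.id] = {"weight": [cf.weight, new.weight]}
            template = template.replace_function(cf, new)
    return template, {"subroutine": "IV", "exhausted": exhausted, "changes": changes}


def overcoverage_step(
    template: PlanTemplate,
    failure: ConditionFailure,
    config: ControllerConfig | None = None,
    step_factor: float | None = None,
) -> tuple[PlanTemplate, dict]:
    """High-side band violation: scale the corresponding target-objective
    weights down one step (factor < 1, floored), relaxing the pressure that
    pushed coverage above the band."""
    cfg = config or ControllerConfig()
    down = 1.0 / step_factor if step_factor is not None else cfg.overcoverage_factor
    structures = ("PTV1", "CTV") if failure.condition == "c1" else ("PTV2",)
    changes: dict = {}
    for cf in list(template.cost_functions):
        if cf.structure not in structures or not cf.is_target or cf.weight is None:
            continue
        new = cf.with_(weight=max(cfg.weight_floor, cf.weight * down))
        changes[cf.id] = {"weight": [cf.weight, new.weight]}
        template = template.replace_function(cf, new)
    return template, {"subroutine": f"{failure.condition}-overcoverage", "changes": changes}


def _apply_adjustment(
    template: PlanTemplate,
    failure: ConditionFailure,
    indices: Mapping[str, float],
    cfg: ControllerConfig,
    step_factor: float | None = None,
) -> tuple[PlanTemplate, dict]:
    if failure.condition in ("c1", "c3") and failure.direction == "high":
        return overcoverage_step(template, failure, cfg, step_factor)
    if failure.condition == "c1":
        return subroutine_I(template, indices, cfg, step_factor)
    if failure.condition == "c3":
        return subroutine_III(template, indices, cfg, step_factor)
    dispatch = {"c2": subroutine_II, "c4": subroutine_IV}
    return dispatch[failure.condition](template, indices, cfg)


# ---------------------------------------------------------------------------
# Outer loop and audit trail


@dataclass
class IterationRecord:
    iteration: int
    phase: str  # "first_step" | "second_step"
    template: dict  # immutable snapshot (serialized)
    isoeffects: dict[str, float]
    engine_status: str
    indices: dict[str, float] = field(default_factory=dict)
    failed_conditions: list[dict] = field(default_factory=list)
    adjustment: dict = field(default_factory=dict)


@dataclass
class AuditTrail:
    records: list[IterationRecord] = field(default_factory=list)

    def append(self, record: IterationRecord) -> None:
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def to_jsonl(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            for rec in self.records:
                fh.write(json.dumps(asdict(rec)) + "\n")
        return path


@dataclass
class AutoplanResult:
    status: str  # "fulfilled" | "budget_exhausted"
    iterations: int  # second-step optimization count
    dose: DoseDistribution  # raw optimizer output of the terminal plan
    normalized_dose: DoseDistribution
    normalization_scale: float
    template: PlanTemplate
    indices: dict[str, float]  # pre-normalization (condition) indices
    normalized_indices: dict[str, float]
    trail: AuditTrail
    failed_conditions: list[ConditionFailure]

    @property
    def fulfilled(self) -> bool:
        return self.status == "fulfilled"


def run_autoplan(
    phantom,
    template: PlanTemplate | None = None,
    config: ControllerConfig | None = None,
    conditions: ConditionSet | None = None,
    engine: SurrogateEngine | None = None,
) -> AutoplanResult:
    """Run the full automatic planning algorithm on one phantom.

    Executes the first step once, then iterates optimize → evaluate →
    adjust (one subroutine per iteration, for the first failed condition)
    until all four conditions hold or the iteration budget is exhausted.
    Deterministic for fixed inputs.
    """
    from .template import default_template

    template = (template or default_template()).copy()
    template.validate()
    cfg = config or ControllerConfig()
    cond = conditions or ConditionSet()
    engine = engine or SurrogateEngine(phantom, template)
    trail = AuditTrail()

    template, fs_results = first_step(template, engine, cfg)
    for i, res in enumerate(fs_results):
        trail.append(
            IterationRecord(
                iteration=0,
                phase="first_step",
                template=template.to_dict() if i == len(fs_results) - 1 else {},
                isoeffects=res.isoeffects,
                engine_status=res.status,
            )
        )

    rx = float(template.prescription.get("PTV1", 7800.0))
    failures: list[ConditionFailure] = []
    result = None
    indices: dict[str, float] = {}
    status = "budget_exhausted"
    iterations = 0
    step_factors = {"c1": cfg.weight_escalation, "c3": cfg.weight_escalation}
    last_direction: dict[str, str | None] = {"c1": None, "c3": None}

    for it in range(1, cfg.max_outer_iterations + 1):
        iterations = it
        result = engine.optimize(template)
        indices = plan_indices(result.dose, phantom, rx)
        failures = evaluate_conditions(indices, cond)
        record = IterationRecord(
            iteration=it,
            phase="second_step",
            template=template.to_dict(),
            isoeffects=result.isoeffects,
            engine_status=result.status,
            indices={k: float(v) for k, v in indices.items()},
            failed_conditions=[asdict(f) for f in failures],
        )
        if not failures:
            trail.append(record)
            status = "fulfilled"
            break
        # one adjustment round per re-optimization: apply the subroutine of
        # every failed condition (in c1..c4 order), so a marginal failure
        # cannot starve the others
        adjustments = []
        for failure in failures:
            factor = None
            if failure.condition in step_factors:
                # contract the step whenever the failure direction reverses:
                # a log-bisection of the coverage band
                last = last_direction[failure.condition]
                if last is not None and last != failure.direction:
                    step_factors[failure.condition] = max(
                        cfg.min_step_factor,
                        step_factors[failure.condition] ** cfg.step_contraction,
                    )
                last_direction[failure.condition] = failure.direction
                factor = step_factors[failure.condition]
            template, adjustment = _apply_adjustment(template, failure, indices, cfg, factor)
            adjustments.append(adjustment)
        record.adjustment = {"applied": adjustments}
        trail.append(record)

    norm_dose, scale = normalize_plan(result.dose, phantom["PTV1"], rx)
    norm_indices = plan_indices(norm_dose, phantom, rx)
    return AutoplanResult(
        status=status,
        iterations=iterations,
        dose=result.dose,
        normalized_dose=norm_dose,
        normalization_scale=scale,
        template=template,
        indices=indices,
        normalized_indices=norm_indices,
        trail=trail,
        failed_conditions=failures,
    )
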