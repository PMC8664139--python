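"""Plan templates: the per-structure cost-function configuration of a plan.

A :class:`PlanTemplate` bundles the ordered cost-function list, the
prescription (78 Gy to PTV1 and 72 Gy to PTV2 in 39 fractions) and the
surrogate optimization settings.  The default template shipped with the
package (``data/default_template.yaml``) encodes the initial clinical
configuration this planning algorithm starts from, including the
deliberately unattainable zRectum serial isoconstraint (800 cGy at power-law
exponent 20) that the first planning step uses as a probe.

Templates round-trip losslessly through YAML; a flat one-line-per-function
text view is available for human diffing.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

from .costs import CostFunction, CostFunctionError

__all__ = [
    "PlanTemplate",
    "OptimizationSettings",
    "TemplateError",
    "default_template",
    "load_template",
    "save_template",
]

#: weight cap for underdose-DVH-type target objectives
CAP_UNDERDOSE = 500.0
#: weight cap for target-penalty and maximum-dose objectives
CAP_PENALTY = 1000.0


class TemplateError(ValueError):
    """Invalid plan template."""


@dataclass(frozen=True)
class OptimizationSettings:
    """Surrogate arc/optimizer geometry settings.

    The arc increment must divide 360; the default of 36° gives ten beam
    directions on the single arc.  Beamlet width and dose-grid spacing are
    desk-scale defaults (4 mm).
    """

    arc_increment_deg: int = 36
    beamlet_width_mm: float = 4.0
    grid_spacing_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.arc_increment_deg <= 0 or 360 % self.arc_increment_deg != 0:
            raise TemplateError(
                f"arc increment must be a positive divisor of 360, got {self.arc_increment_deg}"
            )
        if self.beamlet_width_mm <= 0:
            raise TemplateError("beamlet width must be positive")


@dataclass
class PlanTemplate:
    cost_functions: list[CostFunction]
    prescription: dict = field(
        default_factory=lambda: {"PTV1": 7800.0, "PTV2": 7200.0, "fractions": 39}
    )
    settings: OptimizationSettings = field(default_factory=OptimizationSettings)

    def validate(self) -> None:
        if not self.cost_functions:
            raise TemplateError("template has no cost functions")
        probes = [cf for cf in self.cost_functions if cf.probe]
        if len(probes) != 1 or probes[0].kind != "serial" or probes[0].structure != "zRectum":
            raise TemplateError(
                "template must flag exactly one serial function on zRectum for first-step probing"
            )
        for key in ("PTV1", "PTV2"):
            if self.prescription.get(key, 0) <= 0:
                raise TemplateError(f"prescription dose for {key} must be positive")
        for cf in self.cost_functions:
            if cf.weight is None:
                continue
            cap = CAP_UNDERDOSE if cf.kind == "underdose_dvh" else CAP_PENALTY
            if cf.is_target or cf.kind == "maximum_dose":
                if cf.weight > cap:
                    raise TemplateError(f"{cf.id}: weight {cf.weight} exceeds cap {cap}")

    # -- lookup helpers -----------------------------------------------------

    def find(
        self,
        structure: str | None = None,
        kind: str | None = None,
        threshold_cgy: float | None = None,
        probe: bool | None = None,
    ) -> list[CostFunction]:
        out = []
        for cf in self.cost_functions:
            if structure is not None and cf.structure != structure:
                continue
            if kind is not None and cf.kind != kind:
                continue
            if threshold_cgy is not None and cf.threshold_cgy != threshold_cgy:
                continue
            if probe is not None and cf.probe != probe:
                continue
            out.append(cf)
        return out

    def probe_function(self) -> CostFunction:
        probes = self.find(probe=True)
        if len(probes) != 1:
            raise TemplateError("template has no unique probe function")
        return probes[0]

    def replace_function(self, old: CostFunction, new: CostFunction) -> "PlanTemplate":
        """Return a copy with ``old`` swapped for ``new`` (identity match)."""
        funcs = list(self.cost_functions)
        idx = [i for i, cf in enumerate(funcs) if cf is old or cf == old]
        if not idx:
            raise TemplateError(f"function {old.id} not present in template")
        funcs[idx[0]] = new
        return replace_template(self, cost_functions=funcs)

    def update_functions(self, updates: dict[int, CostFunction]) -> "PlanTemplate":
        funcs = list(self.cost_functions)
        for i, cf in updates.items():
            funcs[i] = cf
        return replace_template(self, cost_functions=funcs)

    def copy(self) -> "PlanTemplate":
        return PlanTemplate(
            cost_functions=list(self.cost_functions),
            prescription=copy.deepcopy(self.prescription),
            settings=self.settings,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        rows = []
        for cf in self.cost_functions:
            row = {"structure": cf.structure, "cost_function": cf.kind, "weight_adjust": cf.weight_mode}
            if cf.weight is not None:
                row["weight"] = cf.weight
            if cf.threshold_cgy is not None:
                row["threshold_cgy"] = cf.threshold_cgy
            row["isoconstraint"] = cf.isoconstraint
            extras = {}
            if cf.k is not None:
                extras["power_law_exponent"] = cf.k
            if cf.alpha is not None:
                extras["cell_sensitivity"] = cf.alpha
            if cf.min_volume_pct is not None:
                extras["minimum_volume_pct"] = cf.min_volume_pct
            if cf.shrink_margin_mm:
                extras["shrink_margin_mm"] = cf.shrink_margin_mm
            if cf.all_voxels:
                extras["optimize_all_voxels"] = True
            if cf.probe:
                extras["first_step_probe"] = True
            if cf.label:
                extras["label"] = cf.label
            if extras:
                row["extras"] = extras
            rows.append(row)
        return {
            "prescription": copy.deepcopy(self.prescription),
            "settings": {
                "arc_increment_deg": self.settings.arc_increment_deg,
                "beamlet_width_mm": self.settings.beamlet_width_mm,
                "grid_spacing_mm": self.settings.grid_spacing_mm,
            },
            "cost_functions": rows,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PlanTemplate":
        funcs = []
        for i, row in enumerate(data.get("cost_functions", [])):
            extras = row.get("extras", {}) or {}
            try:
                funcs.append(
                    CostFunction(
                        structure=row["structure"],
                        kind=row["cost_function"],
                        weight_mode=row.get("weight_adjust", "manual"),
                        weight=row.get("weight"),
                        threshold_cgy=row.get("threshold_cgy"),
                        isoconstraint=row.get("isoconstraint"),
                        k=extras.get("power_law_exponent"),
                        alpha=extras.get("cell_sensitivity"),
                        min_volume_pct=extras.get("minimum_volume_pct"),
                        shrink_margin_mm=extras.get("shrink_margin_mm", 0.0),
                        all_voxels=bool(extras.get("optimize_all_voxels", False)),
                        probe=bool(extras.get("first_step_probe", False)),
                        label=extras.get("label", ""),
                    )
                )
            except (KeyError, CostFunctionError) as exc:
                raise TemplateError(f"cost-function row {i + 1}: {exc}") from exc
        settings = OptimizationSettings(**data.get("settings", {}))
        tpl = cls(
            cost_functions=funcs,
            prescription=data.get("prescription", {"PTV1": 7800.0, "PTV2": 7200.0, "fractions": 39}),
            settings=settings,
        )
        tpl.validate()
        return tpl

    def to_flat_text(self) -> str:
        """One function per line, for human diffing."""
        lines = []
        for cf in self.cost_functions:
            parts = [
                f"{cf.structure:<15}",
                f"{cf.kind:<18}",
                f"{cf.weight_mode:<7}",
                f"w={cf.weight if cf.weight is not None else '-':<7}",
                f"T={cf.threshold_cgy if cf.threshold_cgy is not None else '-':<7}",
                f"iso={cf.isoconstraint:<8g}",
            ]
            extras = []
            if cf.k is not None:
                extras.append(f"k={cf.k:g}")
            if cf.alpha is not None:
                extras.append(f"alpha={cf.alpha:g}")
            if cf.min_volume_pct is not None:
                extras.append(f"min_vol={cf.min_volume_pct:g}%")
            if cf.shrink_margin_mm:
                extras.append(f"shrink={cf.shrink_margin_mm:g}mm")
            if cf.all_voxels:
                extras.append("all_voxels")
            if cf.probe:
                extras.append("probe")
            parts.append(" ".join(extras))
            lines.append("  ".join(parts).rstrip())
        return "\n".join(lines) + "\n"


def replace_template(tpl: PlanTemplate, **changes) -> PlanTemplate:
    base = tpl.copy()
    for key, value in changes.items():
        setattr(base, key, value)
    return base


def load_template(path: str | Path) -> PlanTemplate:
    """Read a template from YAML and validate it."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise TemplateError(f"template file {path} does not contain a mapping")
    return PlanTemplate.from_dict(data)


def save_template(tpl: PlanTemplate, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(tpl.to_dict(), sort_keys=False))
    return path


def default_template() -> PlanTemplate:
    """The shipped initial template (19 cost functions)."""
    text = resources.files("arcplan").joinpath("data/default_template.yaml").read_text()
    return PlanTemplate.from_dict(yaml.safe_load(text))
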