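"""Cost-function library with isoconstraint / isoeffect semantics.

Each cost function is attached to one structure and carries an
*isoconstraint* — the objective value requested for its metric — while the
*isoeffect* is the value that metric actually attains on a given dose
distribution.  Functions come in two weighting modes: ``manual`` functions
act as fixed soft penalties with the listed weight, while ``auto`` functions
act as constraints that the optimizer prioritizes over target coverage
(see :mod:`arcplan.engine`).

Metric definitions (doses in cGy, N = voxels in the evaluation region):

===================  =====================================================
serial               power-law generalized mean ``((1/N) Σ d_i^k)^(1/k)``;
                     large k approaches the maximum dose
target_eud           cell-kill equivalent uniform dose
                     ``-(100/α)·ln((1/N) Σ exp(-α d_i/100))`` with cell
                     sensitivity α per Gy
maximum_dose         ``max_i d_i``
quadratic_overdose   RMS excess over the threshold T:
                     ``sqrt((1/N) Σ max(0, d_i - T)^2)``
overdose_dvh         percent of voxels with ``d_i > T``
underdose_dvh        percent of voxels with ``d_i >= T``
target_penalty       dose level covering the stated minimum volume
                     (``D`` at the minimum-volume percent)
===================  =====================================================

For gradient-based optimization every function also exposes a smooth,
dimensionless penalty with an analytic gradient.  Upper-bound functions
penalize relative excess of the (smoothed) metric over the isoconstraint;
target functions penalize relative deficit below their dose goal.  Counting
metrics are smoothed with a logistic sigmoid of temperature ``dvh_tau_cgy``
for the penalty only — reported isoeffects always use the exact counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .phantom import (
    Margins,
    Phantom,
    StructureMask,
    TARGET_STRUCTURES,
    expand_margin,
    intersect,
    subtract,
)

__all__ = [
    "CostFunction",
    "CostFunctionError",
    "TARGET_KINDS",
    "UPPER_KINDS",
    "eval_cost",
    "isoeffect",
    "penalty_and_grad",
    "shrink_eval_mask",
    "evaluation_mask",
]

KINDS = (
    "serial",
    "target_eud",
    "maximum_dose",
    "quadratic_overdose",
    "overdose_dvh",
    "underdose_dvh",
    "target_penalty",
)

#: kinds that pull dose *up* toward a goal (target objectives)
TARGET_KINDS = frozenset({"target_eud", "underdose_dvh", "target_penalty"})
#: kinds that bound dose from above
UPPER_KINDS = frozenset({"serial", "maximum_dose", "quadratic_overdose", "overdose_dvh"})

#: logistic temperature (cGy) used to smooth DVH counting penalties
DVH_TAU_CGY = 40.0


class CostFunctionError(ValueError):
    """Invalid cost-function configuration or evaluation."""


@dataclass(frozen=True)
class CostFunction:
    """One row of a plan template.

    Parameters mirror the planning-system vocabulary: ``weight_mode`` is
    ``"manual"`` (fixed soft weight) or ``"auto"`` (constraint), ``threshold``
    is the dose level entering DVH/overdose metrics, ``isoconstraint`` the
    requested metric value, and the extras are kind-specific: power-law
    exponent ``k`` (serial), cell sensitivity ``alpha`` per Gy (target EUD),
    ``min_volume_pct`` (target penalty), an evaluation ``shrink_margin_mm``
    and the ``all_voxels`` flag that disables shrink/overlap exclusion.
    """

    structure: str
    kind: str
    weight_mode: str = "manual"
    weight: float | None = None
    threshold_cgy: float | None = None
    isoconstraint: float | None = None
    k: float | None = None
    alpha: float | None = None
    min_volume_pct: float | None = None
    shrink_margin_mm: float = 0.0
    all_voxels: bool = False
    probe: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise CostFunctionError(f"unknown cost-function kind {self.kind!r}")
        if self.weight_mode not in ("manual", "auto"):
            raise CostFunctionError(f"weight mode must be manual/auto, got {self.weight_mode!r}")
        if self.weight_mode == "manual":
            if self.weight is None or self.weight <= 0:
                raise CostFunctionError(
                    f"{self.structure}/{self.kind}: manual functions need a positive weight"
                )
        if self.isoconstraint is None:
            raise CostFunctionError(f"{self.structure}/{self.kind}: isoconstraint is required")
        if self.kind == "serial" and (self.k is None or self.k <= 0):
            raise CostFunctionError(f"{self.structure}/serial: positive power-law exponent k required")
        if self.kind == "target_eud" and (self.alpha is None or self.alpha <= 0):
            raise CostFunctionError(f"{self.structure}/target_eud: positive cell sensitivity required")
        if self.kind == "target_penalty" and (
            self.min_volume_pct is None or not (0 < self.min_volume_pct <= 100)
        ):
            raise CostFunctionError(
                f"{self.structure}/target_penalty: minimum volume percent in (0, 100] required"
            )
        if self.kind in ("quadratic_overdose", "overdose_dvh", "underdose_dvh") and (
            self.threshold_cgy is None or self.threshold_cgy < 0
        ):
            raise CostFunctionError(f"{self.structure}/{self.kind}: dose threshold required")
        if self.shrink_margin_mm < 0:
            raise CostFunctionError("shrink margin must be non-negative")

    @property
    def id(self) -> str:
        """Stable identifier; distinguishes same-kind functions on one
        structure by threshold and exponent (e.g. the two bladder serials)."""
        if self.label:
            return self.label
        parts = [f"{self.structure}/{self.kind}"]
        if self.threshold_cgy is not None:
            parts.append(f"@{self.threshold_cgy:g}")
        if self.k is not None:
            parts.append(f"k{self.k:g}")
        return "".join(parts)

    @property
    def is_target(self) -> bool:
        return self.kind in TARGET_KINDS

    def with_(self, **changes) -> "CostFunction":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# Isoeffects (exact metrics)


def isoeffect(cf: CostFunction, d: np.ndarray) -> float:
    """Exact metric value of ``cf`` on doses ``d`` (cGy) in its region."""
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise CostFunctionError(f"{cf.id}: empty evaluation region")
    if cf.kind == "serial":
        k = float(cf.k)
        dmax = float(d.max())
        if dmax == 0.0:
            return 0.0
        # factor out the max to avoid overflow for large exponents
        return dmax * float(np.mean((d / dmax) ** k)) ** (1.0 / k)
    if cf.kind == "target_eud":
        a = float(cf.alpha)
        dg = d / 100.0  # Gy
        m = float(dg.min())
        return (m - np.log(float(np.mean(np.exp(-a * (dg - m))))) / a) * 100.0
    if cf.kind == "maximum_dose":
        return float(d.max())
    if cf.kind == "quadratic_overdose":
        excess = np.maximum(0.0, d - float(cf.threshold_cgy))
        return float(np.sqrt(np.mean(excess**2)))
    if cf.kind == "overdose_dvh":
        return 100.0 * float(np.mean(d > float(cf.threshold_cgy)))
    if cf.kind == "underdose_dvh":
        return 100.0 * float(np.mean(d >= float(cf.threshold_cgy)))
    if cf.kind == "target_penalty":
        # dose covering the stated minimum volume: D at min_volume_pct
        q = 1.0 - float(cf.min_volume_pct) / 100.0
        return float(np.quantile(d, q, method="linear"))
    raise CostFunctionError(cf.kind)


def eval_cost(cf: CostFunction, dose: np.ndarray, phantom: Phantom) -> float:
    """Isoeffect of ``cf`` on a full-grid dose array, using its evaluation mask."""
    mask = evaluation_mask(cf, phantom)
    if mask.is_empty():
        raise CostFunctionError(f"{cf.id}: evaluation mask is empty after shrink/exclusion")
    return isoeffect(cf, np.asarray(dose)[mask.mask])


# ---------------------------------------------------------------------------
# Smooth penalties with analytic gradients (dimensionless)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


#: relative goal padding for coverage-type target penalties: deficits are
#: measured against a goal 1% above the nominal dose level, so the pull does
#: not vanish exactly at the threshold that coverage is counted at
GOAL_PAD = 1.01


#: dose scale (cGy) that shaping-mode penalties are normalized by, so that
#: low-threshold and high-threshold overdose terms exert comparable pull
SHAPING_REF_CGY = 7800.0


def penalty_and_grad(
    cf: CostFunction, d: np.ndarray, mode: str = "constraint", ref_dose: float = SHAPING_REF_CGY
) -> tuple[float, np.ndarray]:
    """Smooth dimensionless penalty and its gradient w.r.t. the region doses.

    Target kinds penalize dose deficit below their goal; upper kinds
    penalize excess.  ``mode`` selects the reference scale for upper kinds:

    * ``"constraint"`` — excess of the (smoothed) metric relative to the
      isoconstraint; used for enforceable constraints and manual penalties.
    * ``"shaping"`` — excess relative to the dose *threshold*; used for
      constraints whose isoconstraint is out of reach, where they still
      shape the dose without overwhelming the target objectives.

    All penalties are C^1 so that quasi-Newton optimization is well behaved.
    """
    d = np.asarray(d, dtype=float)
    n = d.size
    if n == 0:
        raise CostFunctionError(f"{cf.id}: empty evaluation region")
    c = float(cf.isoconstraint)

    if cf.kind in ("underdose_dvh", "target_penalty"):
        ref = (float(cf.threshold_cgy) if cf.kind == "underdose_dvh" else c) * GOAL_PAD
        deficit = np.maximum(0.0, 1.0 - d / ref)
        p = float(np.mean(deficit**2))
        g = -2.0 * deficit / (ref * n)
        return p, g

    if cf.kind == "target_eud":
        a = float(cf.alpha)
        dg = d / 100.0
        m = float(dg.min())
        w = np.exp(-a * (dg - m))
        s = float(np.mean(w))
        eud = (m - np.log(s) / a) * 100.0
        deficit = max(0.0, 1.0 - eud / c)
        # d eud / d d_i = w_i / (N s)
        g = (-2.0 * deficit / c) * (w / (n * s))
        return deficit**2, g

    if cf.kind == "maximum_dose":
        # per-voxel sum, not a structure mean: a hotspot must not be diluted
        # by the size of the structure it sits in
        excess = np.maximum(0.0, d / c - 1.0)
        p = float(np.sum(excess**2))
        g = 2.0 * excess / c
        return p, g

    if cf.kind == "serial":
        k = float(cf.k)
        dmax = float(d.max())
        if dmax == 0.0:
            return 0.0, np.zeros_like(d)
        s = dmax * float(np.mean((d / dmax) ** k)) ** (1.0 / k)
        excess = max(0.0, s / c - 1.0)
        if excess == 0.0:
            return 0.0, np.zeros_like(d)
        # ds/dd_i = (d_i / s)^(k-1) / N
        g = (2.0 * excess / c) * ((d / s) ** (k - 1.0)) / n
        return excess**2, g

    if cf.kind == "quadratic_overdose":
        t = float(cf.threshold_cgy)
        over = np.maximum(0.0, d - t)
        if mode == "shaping":
            # mean squared excess on the prescription scale
            p = float(np.mean((over / ref_dose) ** 2))
            g = 2.0 * over / (ref_dose**2 * n)
            return p, g
        msq = float(np.mean(over**2))
        q = np.sqrt(msq)
        excess = max(0.0, q / c - 1.0)
        if excess == 0.0 or q == 0.0:
            return 0.0, np.zeros_like(d)
        g = (2.0 * excess / c) * over / (n * q)
        return excess**2, g

    if cf.kind == "overdose_dvh":
        t = float(cf.threshold_cgy)
        s = _sigmoid((d - t) / DVH_TAU_CGY)
        frac = float(np.mean(s))  # smoothed fraction above threshold
        if mode == "shaping":
            g = s * (1.0 - s) / (DVH_TAU_CGY * n)
            return frac, g
        excess = max(0.0, frac - c / 100.0)
        if excess == 0.0:
            return 0.0, np.zeros_like(d)
        g = (2.0 * excess) * s * (1.0 - s) / (DVH_TAU_CGY * n)
        return excess**2, g

    raise CostFunctionError(cf.kind)


# ---------------------------------------------------------------------------
# Evaluation regions


def shrink_eval_mask(
    structure: StructureMask, targets: StructureMask, shrink_margin_mm: float
) -> StructureMask:
    """Evaluation region of an OAR function: the structure minus the targets
    expanded isotropically by the shrink margin.  May be empty; callers that
    require non-empty regions must check."""
    if shrink_margin_mm < 0:
        raise CostFunctionError("shrink margin must be non-negative")
    if targets.is_empty() or shrink_margin_mm == 0:
        expanded = targets
    else:
        expanded = expand_margin(targets, Margins.isotropic(shrink_margin_mm))
    return subtract(structure, expanded, name=structure.name)


def evaluation_mask(cf: CostFunction, phantom: Phantom) -> StructureMask:
    """Region over which ``cf`` is evaluated.

    Target structures and functions flagged "optimize over all voxels"
    evaluate on the full structure; other (OAR) functions retreat from the
    PTV by their shrink margin.
    """
    if cf.structure == "patient":
        struct = phantom["body"]
    else:
        struct = phantom[cf.structure]
    if cf.all_voxels or cf.structure in TARGET_STRUCTURES or cf.structure == "CTV":
        return struct
    targets = phantom.derived.get("PTV")
    if targets is None:
        return struct
    return shrink_eval_mask(struct, targets, cf.shrink_margin_mm)
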