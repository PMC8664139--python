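"""Surrogate single-arc dose engine and constrained-mode fluence optimizer.

The engine stands in for a clinical optimizer at desk scale.  It models a
single 360° arc discretized into equally spaced axial beam directions; each
direction carries a lattice of beamlets (pencil rays) whose dose deposition
is a ray-traced primary with exponential depth attenuation and a Gaussian
lateral penumbra.  Stacking the per-beamlet dose vectors gives a sparse
influence matrix ``D`` mapping nonnegative beamlet fluences ``w`` to voxel
doses ``d = D w`` (cGy).

Fluence optimization emulates the *constrained mode* of a clinical system:
cost functions with automatic weighting act as constraints that take
priority over target coverage, implemented by multiplier escalation on
their penalties.  Constraints that remain violated after escalation — or
that are grossly out of reach at priority weighting, as with the deliberate
first-step probe — are reported as *unattainable* together with the
isoeffect actually achieved, which is exactly the feedback the automatic
planning loop consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from .costs import CostFunction, CostFunctionError, evaluation_mask, isoeffect, penalty_and_grad
from .phantom import Phantom, VoxelGrid
from .template import PlanTemplate

__all__ = [
    "ArcBeamSet",
    "KernelParams",
    "InfluenceMatrix",
    "DoseDistribution",
    "OptimizerConfig",
    "OptimizeResult",
    "EngineError",
    "build_arc",
    "compute_influence",
    "optimize_fluence",
    "SurrogateEngine",
]


class EngineError(ValueError):
    """Invalid engine configuration or state."""


@dataclass(frozen=True)
class ArcBeamSet:
    """A single 360° arc discretized at a fixed gantry-angle increment.

    Beam directions lie in the axial plane through the isocenter.  Gantry
    angle 0° enters from anterior; angles increase clockwise viewed from
    superior (IEC-like).
    """

    gantry_angles_deg: tuple[float, ...]
    beamlet_width_mm: float
    source_axis_distance_mm: float = 1000.0
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        angles = np.asarray(self.gantry_angles_deg)
        if angles.size == 0 or np.any(np.diff(angles) <= 0):
            raise EngineError("gantry angles must be strictly increasing")
        if self.beamlet_width_mm <= 0:
            raise EngineError("beamlet width must be positive")

    @property
    def n_beams(self) -> int:
        return len(self.gantry_angles_deg)


def build_arc(
    grid: VoxelGrid,
    arc_increment_deg: int,
    beamlet_width_mm: float,
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> ArcBeamSet:
    """One full arc with ``360 / increment`` beam directions."""
    if arc_increment_deg <= 0 or 360 % arc_increment_deg != 0:
        raise EngineError(
            f"arc increment must divide 360, got {arc_increment_deg}"
        )
    n = 360 // arc_increment_deg
    angles = tuple(float(i * arc_increment_deg) for i in range(n))
    return ArcBeamSet(angles, float(beamlet_width_mm), isocenter_mm=isocenter_mm)


@dataclass(frozen=True)
class KernelParams:
    """Pencil-beam kernel: attenuation and lateral penumbra.

    ``mu_per_mm`` is the effective linear attenuation of a 6 MV beam in
    water (~0.0046/mm); ``sigma_mm`` the Gaussian penumbra width; entries
    below ``min_rel`` of the entry dose are dropped for sparsity.
    """

    mu_per_mm: float = 0.0046
    sigma_mm: float = 4.0
    cutoff_mm: float = 10.0
    lattice_margin_mm: float = 4.0
    min_rel: float = 1e-3


@dataclass
class InfluenceMatrix:
    """Sparse dose-per-unit-fluence operator restricted to body voxels."""

    matrix: sp.csr_matrix  # (n_body_voxels, n_beamlets), cGy per unit fluence
    body_indices: np.ndarray  # flat indices into the full grid
    grid: VoxelGrid
    beamlet_angle: np.ndarray  # per-beamlet gantry angle (deg)
    beamlet_u_mm: np.ndarray
    beamlet_v_mm: np.ndarray

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]

    def dose(self, w: np.ndarray) -> "DoseDistribution":
        """Full-grid dose (cGy) from a fluence vector; zero outside the body."""
        w = np.asarray(w, dtype=float)
        if w.shape != (self.n_beamlets,):
            raise EngineError(f"fluence vector must have shape ({self.n_beamlets},)")
        if np.any(w < 0):
            raise EngineError("fluence weights must be nonnegative")
        d = np.zeros(int(np.prod(self.grid.shape)))
        d[self.body_indices] = self.matrix @ w
        return DoseDistribution(d.reshape(self.grid.shape), self.grid)


@dataclass
class DoseDistribution:
    """Dose in cGy per voxel on a :class:`VoxelGrid`."""

    array: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=float)
        if self.array.shape != tuple(self.grid.shape):
            raise EngineError("dose array shape does not match grid")

    def scaled(self, factor: float) -> "DoseDistribution":
        return DoseDistribution(self.array * factor, self.grid)


def compute_influence(
    phantom: Phantom,
    arc: ArcBeamSet,
    kernel: KernelParams | None = None,
) -> InfluenceMatrix:
    """Ray-traced influence matrix for one arc on a phantom.

    For each beam direction the body voxels are expressed in beam-frame
    coordinates (depth ``t`` along the ray, lateral ``u`` across the axial
    plane, ``v`` along z).  Each beamlet deposits
    ``exp(-mu * depth) * exp(-((u-u_j)^2 + (v-v_j)^2) / (2 sigma^2))``
    cGy per unit fluence, with the depth measured from the body surface
    along that beamlet's ray corridor.  The beamlet lattice covers the PTV
    projection plus a small margin.  Deterministic for fixed inputs.
    """
    kernel = kernel or KernelParams()
    grid = phantom.grid
    body = phantom["body"].mask
    if "PTV" not in phantom.derived:
        raise EngineError("phantom must carry derived structures (PTV) to build the influence")
    ptv = phantom.derived["PTV"].mask

    iso = np.asarray(arc.isocenter_mm)
    # the isocenter must lie inside the body contour
    ijk = np.round((iso - np.asarray(grid.origin)) / np.asarray(grid.spacing)).astype(int)
    if np.any(ijk < 0) or np.any(ijk >= np.asarray(grid.shape)) or not body[tuple(ijk)]:
        raise EngineError("isocenter lies outside the body contour")

    body_idx = np.flatnonzero(body.ravel())
    ii, jj, kk = np.unravel_index(body_idx, grid.shape)
    xs = grid.axis_coords(0)[ii] - iso[0]
    ys = grid.axis_coords(1)[jj] - iso[1]
    zs = grid.axis_coords(2)[kk] - iso[2]

    pi, pj, pk = np.nonzero(ptv)
    px = grid.axis_coords(0)[pi] - iso[0]
    py = grid.axis_coords(1)[pj] - iso[1]
    pz = grid.axis_coords(2)[pk] - iso[2]

    width = arc.beamlet_width_mm
    half = kernel.cutoff_mm
    reach = int(np.ceil(half / width))

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    b_angle: list[float] = []
    b_u: list[float] = []
    b_v: list[float] = []
    col0 = 0

    for ang in arc.gantry_angles_deg:
        rad = np.deg2rad(ang)
        # gantry 0 = source anterior, beam travels toward -y
        dir_x, dir_y = np.sin(rad), -np.cos(rad)
        ux, uy = np.cos(rad), np.sin(rad)
        t = xs * dir_x + ys * dir_y  # depth coordinate along the beam
        u = xs * ux + ys * uy
        v = zs

        # beamlet lattice covering the PTV projection (+ margin)
        pu = px * ux + py * uy
        pv = pz
        mar = kernel.lattice_margin_mm
        u_lat = _lattice(pu.min() - mar, pu.max() + mar, width)
        v_lat = _lattice(pv.min() - mar, pv.max() + mar, width)

        # ray-corridor entry depth: minimum body t per (u, v) bin
        ub = np.round((u - u_lat[0]) / width).astype(int)
        vb = np.round((v - v_lat[0]) / width).astype(int)
        nub = int(ub.max()) + 2 + reach
        nvb = int(vb.max()) + 2 + reach
        ub0 = np.clip(ub, 0, nub - 1)
        vb0 = np.clip(vb, 0, nvb - 1)
        flat_bin = ub0 * nvb + vb0
        entry = np.full(nub * nvb, np.inf)
        np.minimum.at(entry, flat_bin, t)
        # fill bins with no body voxel from neighbors via the global minimum
        depth = t - entry[flat_bin]
        primary = np.exp(-kernel.mu_per_mm * np.maximum(depth, 0.0))

        # bucket voxels by lattice bin for neighborhood gathers
        order = np.argsort(flat_bin, kind="stable")
        sorted_bins = flat_bin[order]
        bounds = np.searchsorted(sorted_bins, np.arange(nub * nvb + 1))

        inv_two_sigma2 = 1.0 / (2.0 * kernel.sigma_mm**2)
        for a, u_j in enumerate(u_lat):
            au = int(np.round((u_j - u_lat[0]) / width))
            for b, v_j in enumerate(v_lat):
                bv = int(np.round((v_j - v_lat[0]) / width))
                idx_chunks = []
                for da in range(max(0, au - reach), min(nub, au + reach + 1)):
                    lo = bounds[da * nvb + max(0, bv - reach)]
                    hi = bounds[da * nvb + min(nvb - 1, bv + reach) + 1]
                    if hi > lo:
                        idx_chunks.append(order[lo:hi])
                if not idx_chunks:
                    continue
                sel = np.concatenate(idx_chunks)
                du = u[sel] - u_j
                dv = v[sel] - v_j
                lat = np.exp(-(du**2 + dv**2) * inv_two_sigma2)
                dose = primary[sel] * lat
                keep = dose > kernel.min_rel
                if not np.any(keep):
                    continue
                rows.append(sel[keep])
                cols.append(np.full(int(keep.sum()), col0))
                vals.append(dose[keep])
                b_angle.append(ang)
                b_u.append(float(u_j))
                b_v.append(float(v_j))
                col0 += 1

    if col0 == 0:
        raise EngineError("no beamlet deposits dose in the body")
    matrix = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(body_idx.size, col0),
    )
    return InfluenceMatrix(
        matrix=matrix,
        body_indices=body_idx,
        grid=grid,
        beamlet_angle=np.asarray(b_angle),
        beamlet_u_mm=np.asarray(b_u),
        beamlet_v_mm=np.asarray(b_v),
    )


def _lattice(lo: float, hi: float, step: float) -> np.ndarray:
    n = max(1, int(np.ceil((hi - lo) / step)) + 1)
    center = (lo + hi) / 2.0
    return center + step * (np.arange(n) - (n - 1) / 2.0)


# ---------------------------------------------------------------------------
# Constrained-mode fluence optimization


@dataclass(frozen=True)
class OptimizerConfig:
    """Multiplier-escalation settings for constrained-mode emulation.

    ``lambda0`` is the priority weight given to every automatic-weighting
    (constraint) function on the first pass; violated constraints are
    escalated by ``escalation_factor`` up to ``max_escalations`` times.  A
    constraint still violated beyond the feasibility tolerance afterwards —
    or violated by more than ``gross_ratio`` times its isoconstraint on the
    first pass, in which case escalation is pointless and the goal is
    declared out of reach immediately — yields an ``unattainable`` status.
    """

    lambda0: float = 100.0
    escalation_factor: float = 10.0
    max_escalations: int = 4
    feas_rel_tol: float = 0.005
    feas_abs_tol: float = 1.0  # cGy for dose-valued metrics, pp for percent
    gross_ratio: float = 2.0
    maxiter_detection: int = 80
    maxiter_first: int = 150
    maxiter_escalation: int = 60
    seed: int = 0  # kept for interface stability; initialization is deterministic


@dataclass
class OptimizeResult:
    w: np.ndarray
    status: str  # "feasible" | "unattainable"
    dose: DoseDistribution
    isoeffects: dict[str, float]
    unattainable: list[str] = field(default_factory=list)
    unattainable_isoeffects: dict[str, float] = field(default_factory=dict)
    n_solves: int = 0

    @property
    def feasible(self) -> bool:
        return self.status == "feasible"


def _constraint_violation(cf: CostFunction, effect: float, cfg: OptimizerConfig) -> float:
    """Relative violation of an upper-bound constraint (0 when satisfied)."""
    c = float(cf.isoconstraint)
    slack = max(cfg.feas_rel_tol * abs(c), cfg.feas_abs_tol)
    if effect <= c + slack:
        return 0.0
    return (effect - c) / max(abs(c), 1e-9)


def optimize_fluence(
    influence: InfluenceMatrix,
    template: PlanTemplate,
    phantom: Phantom,
    config: OptimizerConfig | None = None,
    w0: np.ndarray | None = None,
) -> OptimizeResult:
    """Optimize beamlet fluences for a template in constrained mode.

    Manual-weight functions contribute fixed soft penalties; auto-weight
    functions are constraints enforced by multiplier escalation.  Returns
    the fluences, the dose, the exact isoeffect of every cost function, and
    a feasibility status; ``unattainable`` carries the constraints whose
    isoconstraints could not be met together with their achieved isoeffects
    (for the first-pass gross case, the first-pass isoeffect — the value the
    optimization "halts" at).
    """
    cfg = config or OptimizerConfig()
    if not template.cost_functions:
        raise EngineError("template has no cost functions")

    # resolve evaluation regions once (indices into the body-voxel vector)
    body_pos = {int(f): i for i, f in enumerate(influence.body_indices)}
    regions: list[np.ndarray] = []
    for cf in template.cost_functions:
        mask = evaluation_mask(cf, phantom)
        if mask.is_empty():
            raise CostFunctionError(f"{cf.id}: evaluation mask is empty after shrink/exclusion")
        flat = np.flatnonzero(mask.mask.ravel())
        reg = np.asarray([body_pos[f] for f in flat if f in body_pos], dtype=int)
        if reg.size == 0:
            raise CostFunctionError(f"{cf.id}: evaluation mask has no body voxels")
        regions.append(reg)

    funcs = template.cost_functions
    autos = [i for i, cf in enumerate(funcs) if cf.weight_mode == "auto"]
    targets = [i for i, cf in enumerate(funcs) if cf.is_target]

    M = influence.matrix
    n = M.shape[1]

    if not targets:
        # nothing pulls dose up: zero fluence satisfies every upper bound
        w = np.zeros(n)
        dose_body = M @ w
        effects = {
            cf.id: isoeffect(cf, dose_body[reg]) for cf, reg in zip(funcs, regions)
        }
        return OptimizeResult(
            w=w, status="feasible", dose=influence.dose(w), isoeffects=effects, n_solves=0
        )

    def objective_factory(lambdas: dict[int, float], modes: dict[int, str]):
        def objective(w: np.ndarray) -> tuple[float, np.ndarray]:
            d = M @ w
            total = 0.0
            g_d = np.zeros_like(d)
            for i, (cf, reg) in enumerate(zip(funcs, regions)):
                if i in lambdas:
                    coeff = lambdas[i]
                    if coeff == 0.0:
                        continue
                    mode = modes.get(i, "constraint")
                else:
                    coeff = float(cf.weight)
                    mode = "constraint"
                p, g = penalty_and_grad(cf, d[reg], mode=mode)
                if p == 0.0 and not np.any(g):
                    continue
                total += coeff * p
                g_d[reg] += coeff * g
            return total, M.T @ g_d

        return objective

    if w0 is None:
        # deterministic start: uniform fluence scaled to the PTV1 prescription
        w = np.ones(n)
        d0 = M @ w
        ptv1_idx = [i for i, cf in enumerate(funcs) if cf.structure == "PTV1"]
        ptv1_reg = regions[ptv1_idx[0]] if ptv1_idx else np.arange(d0.size)
        mean0 = float(d0[ptv1_reg].mean())
        rx = float(template.prescription.get("PTV1", 7800.0))
        w *= rx / max(mean0, 1e-9)
    else:
        w = np.asarray(w0, dtype=float).copy()

    def solve(objective, w_start: np.ndarray, maxiter: int) -> np.ndarray:
        res = scipy.optimize.minimize(
            objective,
            w_start,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * n,
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-12},
        )
        return np.maximum(res.x, 0.0)

    def exact_effects(d_vec: np.ndarray) -> dict[int, float]:
        return {i: isoeffect(cf, d_vec[reg]) for i, (cf, reg) in enumerate(zip(funcs, regions))}

    # --- detection pass: manual objectives only.  The isoeffects of this
    # solution are the "natural" metric values the constraints are judged
    # against: a constraint whose goal is grossly out of reach here is
    # reported unattainable at this isoeffect (the optimization halt the
    # first planning step exploits) and demoted to a shaping penalty.
    n_solves = 0
    detect_obj = objective_factory({i: 0.0 for i in autos}, {})
    w = solve(detect_obj, w, cfg.maxiter_detection)
    n_solves += 1
    detect_effects = exact_effects(M @ w)

    gross: set[int] = set()
    for i in autos:
        c = float(funcs[i].isoconstraint)
        if detect_effects[i] > cfg.gross_ratio * max(c, cfg.feas_abs_tol):
            gross.add(i)

    lambdas: dict[int, float] = {}
    modes: dict[int, str] = {}
    for i in autos:
        if i in gross:
            # shaping is threshold-relative; aggregate kinds without a
            # threshold (serial, maximum dose) are dropped for this solve
            has_threshold = funcs[i].threshold_cgy is not None
            lambdas[i] = cfg.lambda0 if has_threshold else 0.0
            modes[i] = "shaping"
        else:
            lambdas[i] = cfg.lambda0
            modes[i] = "constraint"

    w = solve(objective_factory(lambdas, modes), w, cfg.maxiter_first)
    n_solves += 1
    effects = exact_effects(M @ w)

    for _ in range(cfg.max_escalations):
        violated = [
            i
            for i in autos
            if i not in gross and _constraint_violation(funcs[i], effects[i], cfg) > 0.0
        ]
        if not violated:
            break
        for i in violated:
            lambdas[i] *= cfg.escalation_factor
        w = solve(objective_factory(lambdas, modes), w, cfg.maxiter_escalation)
        n_solves += 1
        effects = exact_effects(M @ w)

    unattainable = sorted(
        set(gross) | {i for i in autos if _constraint_violation(funcs[i], effects[i], cfg) > 0.0}
    )
    status = "feasible" if not unattainable else "unattainable"
    report = {
        funcs[i].id: (detect_effects[i] if i in gross else effects[i]) for i in unattainable
    }
    return OptimizeResult(
        w=w,
        status=status,
        dose=influence.dose(w),
        isoeffects={funcs[i].id: effects[i] for i in range(len(funcs))},
        unattainable=[funcs[i].id for i in unattainable],
        unattainable_isoeffects=report,
        n_solves=n_solves,
    )


class SurrogateEngine:
    """Convenience wrapper binding a phantom to its arc and influence matrix.

    The influence depends only on geometry, so it is computed once per
    phantom and reused across the planning loop's re-optimizations.
    """

    def __init__(
        self,
        phantom: Phantom,
        template: PlanTemplate,
        kernel: KernelParams | None = None,
        optimizer_config: OptimizerConfig | None = None,
    ) -> None:
        self.phantom = phantom
        self.kernel = kernel or KernelParams()
        self.config = optimizer_config or OptimizerConfig()
        iso = _centroid_mm(phantom)
        self.arc = build_arc(
            phantom.grid,
            template.settings.arc_increment_deg,
            template.settings.beamlet_width_mm,
            isocenter_mm=iso,
        )
        self.influence = compute_influence(phantom, self.arc, self.kernel)
        self._warm: np.ndarray | None = None

    def optimize(self, template: PlanTemplate, warm_start: bool = True) -> OptimizeResult:
        w0 = self._warm if warm_start else None
        result = optimize_fluence(self.influence, template, self.phantom, self.config, w0=w0)
        self._warm = result.w
        return result


def _centroid_mm(phantom: Phantom) -> tuple[float, float, float]:
    mask = phantom.derived.get("PTV", phantom.primaries["CTV"]).mask
    idx = np.argwhere(mask)
    center = idx.mean(axis=0)
    return tuple(
        float(phantom.grid.origin[a] + phantom.grid.spacing[a] * center[a]) for a in range(3)
    )
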