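# Methods

This note documents the models, algorithms and design choices behind
`arcplan`: an automatic, closed-loop treatment-planning system for prostate
VMAT with a single 360° arc, running end-to-end against a self-contained
surrogate dose engine on synthetic pelvic phantoms.

## The planning problem

A prostate VMAT plan must deliver 78 Gy to PTV1 (the planning target volume
excluding the rectum) and 72 Gy to PTV2 (the PTV/rectum overlap) in 39
fractions, while limiting dose to the rectum, bladder, urethra, femoral
heads and the rest of the patient.  The planner controls a template of
per-structure cost functions (commercial-TPS vocabulary: serial EUD,
target EUD, maximum dose, quadratic overdose, overdose/underdose DVH,
target penalty), each carrying an *isoconstraint* — the requested metric
value.  The *isoeffect* is the value that metric attains on the current
dose.  Inverse planning is iterative: optimize, inspect the dose indices,
adjust the template, repeat.  `arcplan` automates that loop for the
single-arc prostate case.

The automatic algorithm has two steps:

1. **First step — per-case isoconstraint determination.**  The initial
   template deliberately sets the zRectum serial isoconstraint (800 cGy at
   power-law exponent 20) far below what any plan can achieve next to a
   78 Gy target, so the optimizer halts and reports the goal unattainable
   together with the achieved isoeffect `e0`.  The isoconstraint is updated
   to `0.9·e0`, optimization is rerun to completion, and the isoconstraint
   is finally pinned at the achieved isoeffect `e1` (a fixed point).  The
   two bladder serial isoconstraints are simultaneously set to their
   isoeffects reduced by 40%.  This tailors the OAR constraints to each
   case's geometry before the main loop starts.

2. **Second step — condition loop.**  Re-optimize, compute dose indices,
   and check four conditions on the raw (un-normalized) optimizer output:
   c1: 93% ≤ V_78Gy(PTV1) ≤ 97%; c2: D_2%(patient) ≤ 81.7 Gy (checked only
   once c1 holds); c3: 93% ≤ V_72Gy(PTV2) ≤ 97%; c4: D_1%(urethra) ≤ 81 Gy.
   Each failed condition triggers its subroutine: I and III double the
   corresponding target-objective weights (caps 500 for underdose-DVH and
   1000 for target-penalty weights) and, once every weight is capped,
   loosen the competing OAR parameters (isoconstraints ×1.05, shrink
   margins +2 mm, bladder weights halved, patient quadratic-overdose
   isoconstraint +1 cGy, rectal quadratic-overdose isoconstraints +2 cGy,
   PTV2 overdose-DVH isoconstraint +5 pp); II and IV double the patient's
   resp. urethra's maximum-dose weight (cap 1000).  Coverage above the 97%
   band is handled by scaling the same target weights down one step
   (factor 0.8, floored at 1).  One adjustment round is applied per
   re-optimization: the subroutine of every failed condition, in c1..c4
   order.  When a coverage condition's failure direction reverses
   (low ↔ high), its weight-step factor contracts (square-roots toward 1,
   floored at 1.05) — a log-space bisection of the coverage band that
   replaces endless fixed-step oscillation around it; the first call is
   always the full ×2 step and the caps are unaffected.  Successive
   templates differ only in parameters owned by the subroutines applied
   that iteration, and every change is recorded with before/after values
   in the audit trail.  The loop terminates when all four conditions hold,
   or after 30 iterations (`budget_exhausted`).

Conditions are evaluated before normalization; the 93–97% coverage band
would be vacuous on a normalized plan (normalization forces
V at the prescription to ~95% by construction).  Normalization — scaling
the dose so 95% of PTV1 receives the prescription — is applied only to the
final plan for reporting (HI, CI, DVH export).

## The surrogate dose engine

The engine stands in for a commercial optimizer at desk scale; nothing in
it is a Monte Carlo calculation.

**Geometry.**  One 360° arc discretized at a 36° increment (ten axial beam
directions; the increment must divide 360 and is configurable).  Each
direction carries a lattice of 4 mm pencil beamlets covering the PTV
projection plus a 4 mm margin.  The dose grid is 4 mm, ~48×48×32 voxels.
These are deliberately coarser than clinical practice (2 mm beamlets and
grid) so that a 20-case closed-loop suite runs in minutes on one CPU; the
template records both settings.

**Dose model.**  Beamlet `j` deposits
`exp(-μ·depth) · exp(-((u-u_j)² + (v-v_j)²) / 2σ²)` cGy per unit fluence
at each body voxel, where depth is measured from the body surface along the
beamlet's ray corridor, `μ = 0.0046/mm` is the effective attenuation of a
6 MV beam in water, and `σ = 4 mm` is the Gaussian penumbra (chosen at the
upper end of clinical 6 MV penumbra widths; entries below 10⁻³ of the
entry dose are dropped).  Stacking beamlets gives a sparse influence
matrix `D`; dose is linear in the nonnegative fluence vector, `d = D w`.
The phantom is uniform water inside the body contour.

**Cost functions.**  The engine implements the template vocabulary with
committed formulas (doses in cGy, N voxels in the evaluation region):
serial `((1/N)Σ dᵢᵏ)^{1/k}`; target EUD `-(100/α)·ln((1/N)Σ e^{-α dᵢ/100})`
with cell sensitivity α per Gy; maximum dose `max dᵢ`; quadratic overdose
`sqrt((1/N)Σ max(0, dᵢ-T)²)` (RMS excess over the threshold T); overdose /
underdose DVH as exact percent counts; target penalty as the dose covering
the stated minimum volume (a quantile).  OAR functions are evaluated on
the structure minus the PTV expanded by the function's shrink margin;
target structures (CTV, PTV1, PTV2, the embedded urethra) and functions
flagged "optimize over all voxels" use the full structure.

**Optimization surrogates.**  For gradient-based optimization each
function exposes a smooth, dimensionless C¹ penalty with an analytic
gradient (validated against central finite differences): quadratic
relative deficits for target functions (measured against a goal padded 1%
above the nominal level, so the pull does not vanish exactly at the
counting threshold), quadratic relative excess of the aggregate metric for
serial/quadratic-overdose/DVH bounds, a per-voxel (not structure-mean)
quadratic excess for maximum-dose functions so hotspots are not diluted by
structure size, and a logistic smoothing (temperature 40 cGy) for DVH
counts.  Reported isoeffects always use the exact metrics.

**Constrained mode.**  Manual-weight functions are fixed soft penalties.
Auto-weight functions are constraints handled in three stages:

1. *Detection pass* — solve with manual objectives only and measure each
   constraint's natural isoeffect.  A constraint violated by more than 2×
   its isoconstraint here is declared **unattainable immediately** and
   reported at this natural isoeffect; this is the halt-and-report
   behavior the first planning step exploits.
2. *Main pass* — attainable constraints enter at priority weight
   λ₀ = 100 with isoconstraint-relative penalties; unattainable ones are
   demoted to threshold-based *shaping* penalties normalized on the
   prescription scale (so a 2340 cGy and a 7800 cGy overdose term exert
   comparable, bounded pull), or dropped for the solve if they have no
   threshold (the serial probe).
3. *Escalation* — constraints still violated beyond tolerance (0.5%
   relative or 1 cGy/1 pp absolute) have their multipliers escalated ×10,
   up to 4 rounds, warm-starting each solve.

Solves use L-BFGS-B on `w ≥ 0` with the analytic gradient `Dᵀ∂p/∂d`,
deterministic uniform initialization scaled to the PTV1 prescription, and
iteration caps (80/150/60 for detection/main/escalation).  Everything is
deterministic for fixed inputs; re-running a case reproduces the audit
trail bitwise.

Without the demotion step, a grossly unattainable constraint (e.g. RMS
excess over 2340 cGy ≤ 20 cGy for a structure abutting a 72 Gy target)
would dominate the objective at any priority weight and erase target
coverage; with it, such constraints still shape the OAR dose while the
loop's shrink-margin and isoconstraint loosening retain real leverage.

## The synthetic phantom generator

Phantoms emulate male pelvic anatomy on a regular grid (x = patient left,
y = anterior, z = superior; voxel-center coordinates): an elliptical body
cylinder (~86×72 mm semi-axes), an ellipsoidal prostate CTV (18–24 mm
radii) centered slightly posterior, an elliptical rectal cylinder directly
posterior whose anterior wall reaches 4–8 mm past the CTV surface
(abutting contours interpenetrate on a coarse grid; the reach guarantees
the PTV∩rectum overlap spans ≥~50 voxels so the 93–97% band is at least a
couple of voxels wide), a bladder resting on the anterior–superior CTV
surface, a urethra of 8–9 mm radius running through the gland (thickened
so it spans ~100 voxels at 4 mm), and 16–20 mm femoral heads placed
laterally.  One integer seed drives every uniform draw; derived structures
follow the margin recipe: PTV = CTV + 8 mm (5 mm posterior), PTV1 = PTV \
rectum, PTV2 = PTV ∩ rectum, and zRectum = (rectum + 5 mm posterior) \
(PTV + 3 mm).

Margin expansion uses an axis-aligned ellipsoidal metric
(Σ(Δu/m_u)² ≤ 1 with direction-dependent margins, voxel centers tested),
implemented as an FFT convolution with the exact structuring element and
verified against a pairwise-distance oracle.

What the generator does **not** model: heterogeneous densities (bone, gas),
CT appearance, inter-patient shape variation beyond the uniform parameter
ranges, organ deformation, and contouring noise.  Passing the closed-loop
suite therefore demonstrates the *algorithm's* behavior — probing,
condition gating, escalation, caps, termination — under controlled
geometry, not clinical dosimetric accuracy.

## Dose metrics

`V_x` is an exact voxel count; `D_y%` is the ascending-quantile of the
structure doses at fraction `1 - y/100` with linear interpolation between
voxel ranks (so D_100% is the minimum and D_50% the median); `D_1cc`
converts the volume to a percent first.  Indices are computed from sorted
voxels, never from binned curves; DVH exports default to 10 cGy bins.
HI = D_1%/D_95% on PTV1, and CI = TV_PD²/(TV·V_PD) with TV the PTV1
volume, TV_PD its part covered by the prescription isodose and V_PD the
prescription isodose volume inside the body (all in cc).  Normalization
scales the dose by `prescription / D_95%(PTV1)` and is idempotent.

## Numerical choices and degenerate inputs

- Serial metrics factor out the maximum dose before exponentiating, so
  exponent 20 at 9000 cGy does not overflow.
- Quadratic-overdose gradients guard the `q = 0` point; relu² penalties
  are C¹ at their kinks.
- A template with only upper-bound functions optimizes to `w = 0`
  (trivially feasible); an empty template is an error, as is a cost
  function whose evaluation region is empty after shrink/exclusion.
- Expansion by margins smaller than the voxel spacing is the identity
  (voxel centers are tested); the fine-grid geometry checks use a 1 mm
  grid where the 8/5/3 mm recipe is exactly resolvable.
- Equality on the coverage bands is inclusive; condition values are
  floats compared directly (no rounding).

## Problem sizes and defaults

The canonical suite is 20 phantoms (seeds 1–20) at the default 4 mm grid,
~42 000 body voxels and ~2 700 beamlets per case; a case optimizes in a
few seconds per outer iteration and the whole suite completes in roughly
ten minutes on one CPU.  The fine-grid geometry case uses a 96×96×64 grid
at 1 mm with a spherical 14 mm CTV.  Controller defaults: weight
escalation ×2 per iteration, caps 500/1000, loosening steps as listed
above, outer budget 30 iterations, probe reduction 10%, bladder reduction
40%.

## Known limitations

- The engine's constrained mode is a penalty/multiplier emulation; it has
  no duality-based optimality certificate, and "unattainable" is defined
  operationally (gross violation at detection, or residual violation
  after bounded escalation).
- CI of the surrogate plans (~0.8) sits below clinical single-arc values
  (~0.89): ten beam directions and 4 mm beamlets bound achievable
  conformity.  HI (~1.03) is comparable to clinical plans.
- Monitor units, control-point sequencing, segment shapes and delivery
  -time effects are out of scope; the fluence vector is the final output.
- The four-condition check is exact voxel counting on a coarse grid, so
  condition 3 is sensitive to the PTV2 voxel count; the generator
  guarantees enough overlap resolution for the band to be reachable.
- At 4 mm resolution the PTV2 dose distribution is a near-uniform block
  (spread ~100 cGy), so V_72Gy responds almost discontinuously to weight
  steps as the block crosses the 7200 cGy threshold.  The step bisection
  lands every suite case inside the bands, but a minority of cases need
  more than nine outer iterations to do so — a coarse-scale artifact a
  clinical-resolution engine, with its smooth DVH response, does not
  share.
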