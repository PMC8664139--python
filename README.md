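# arcplan

Automatic treatment planning for prostate cancer with single-arc VMAT,
implemented as a closed-loop system over a self-contained surrogate dose
engine and synthetic pelvic phantoms.

## The problem

Inverse planning for VMAT is iterative trial and error: the planner sets
per-structure cost functions (each with an *isoconstraint* — its requested
objective value), optimizes, inspects the dose–volume histogram, adjusts,
and repeats.  Plan quality varies with the planner, and for prostate the
plan should use a **single** 360° arc so treatment stays short enough for
intrafraction motion management.  `arcplan` automates the loop for that
case: it determines patient-specific OAR isoconstraints up front from
*isoeffect* feedback (the value a cost-function metric actually attains),
then iterates optimization and rule-based parameter adjustment until four
dose-index conditions hold:

| # | Structure | Condition |
|---|-----------|-----------|
| 1 | PTV1 | 93% ≤ V_78Gy ≤ 97% |
| 2 | patient (body) | D_2% ≤ 81.7 Gy (checked once 1 holds) |
| 3 | PTV2 | 93% ≤ V_72Gy ≤ 97% |
| 4 | urethra | D_1% ≤ 81 Gy |

with V_xGy the percent of a structure receiving at least x Gy and D_y% the
minimum dose of its hottest y%.  The prescription is 78 Gy / 72 Gy to
PTV1 / PTV2 (the PTV outside / inside the rectum) in 39 fractions; final
plans are normalized so 95% of PTV1 receives the prescription, and
reported with the heterogeneity and conformity indices

    HI = D_1% / D_95%        CI = TV_PD² / (TV · V_PD)

on PTV1 (TV the target volume, TV_PD its part covered by the prescription
isodose, V_PD the prescription isodose volume).

Everything runs against a desk-scale surrogate: a ray-traced pencil-beam
dose model on a 4 mm grid with a constrained-mode fluence optimizer, and a
seeded generator of pelvic phantoms.  See `docs/methods.md` for the models,
formulas and design choices, and their limits.

## Worked example

```bash
python examples/03_autoplan_case.py
```

```
status: fulfilled after 6 iterations
  it 1  V78= 81.5%  D2%(body)=  7873 cGy  V72= 65.5%  D1%(urethra)=  8019 cGy  failed: c1,c3
  it 2  V78= 85.6%  D2%(body)=  7883 cGy  V72= 65.5%  D1%(urethra)=  8013 cGy  failed: c1,c3
  it 3  V78= 88.9%  D2%(body)=  7892 cGy  V72= 65.5%  D1%(urethra)=  8051 cGy  failed: c1,c3
  it 4  V78= 91.2%  D2%(body)=  7895 cGy  V72= 65.5%  D1%(urethra)=  8061 cGy  failed: c1,c3
  it 5  V78= 91.3%  D2%(body)=  7897 cGy  V72= 65.5%  D1%(urethra)=  8062 cGy  failed: c1,c3
  it 6  V78= 95.5%  D2%(body)=  7889 cGy  V72= 96.6%  D1%(urethra)=  8031 cGy  failed: -
normalization scale: 0.9994
HI (D1%/D95% on PTV1): 1.034
CI (TV_PD^2/(TV*V_PD)): 0.875
All four conditions hold on the terminal plan; the audit trail stored every iteration.
```

Reading it: the first optimization (after the first step has already
tailored the zRectum and bladder isoconstraints to this anatomy) covers
only 81.5% of PTV1 at 78 Gy, so the target-objective weights escalate
toward their caps over iterations 1–5; once capped, the loosening phase
retreats the rectal constraints (isoconstraints and shrink margins) and at
iteration 6 both coverage conditions land inside their 93–97% bands with
the body and urethra limits already satisfied.  HI ≈ 1.03 means a
near-homogeneous target dose; CI ≈ 0.88 means the 78 Gy isodose hugs PTV1
with little spill.

The other examples cover phantom generation, a single optimization with
the initial template (showing the deliberate zRectum halt used for
probing), a small batch suite, and DVH export.  A thin CLI wraps the same
library calls:

```bash
arcplan plan --seed 1 --out runs/case1        # exit 0 iff conditions met
arcplan batch --n 20 --base-seed 1 --out runs/suite
arcplan metrics --dose runs/case1/dose_cgy.npy --phantom runs/case1/phantom
arcplan validate-template my_template.yaml
```

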