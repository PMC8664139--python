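"""One surrogate optimization with the initial template.

Builds the influence matrix for a single 36-degree-increment arc, runs the
constrained-mode fluence optimizer once, and prints the isoeffect of each
cost function next to its isoconstraint.  The zRectum serial function is
deliberately unattainable in the initial template (the first planning step
uses that halt as a probe), so expect an 'unattainable' status here.
"""
from arcplan import SurrogateEngine, default_template, generate_phantom
from arcplan.dvh import plan_indices

phantom = generate_phantom(seed=1)
template = default_template()
engine = SurrogateEngine(phantom, template)
result = engine.optimize(template)

print("status:", result.status)
print("unattainable goals:", result.unattainable)
print(f"{'cost function':42s} {'isoconstraint':>13s} {'isoeffect':>10s}")
for cf in template.cost_functions:
    print(f"{cf.id:42s} {cf.isoconstraint:13.1f} {result.isoeffects[cf.id]:10.1f}")
indices = plan_indices(result.dose, phantom)
print("\ncondition indices of this first (uncorrected) plan:")
for key in ("PTV1_V78Gy_pct", "body_D2pct_cGy", "PTV2_V72Gy_pct", "urethra_D1pct_cGy"):
    print(f"  {key} = {indices[key]:.1f}")
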