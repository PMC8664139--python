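"""A small fixed-seed suite: the cohort-style view of the system.

Plans several independent phantoms and prints the outcome table — status,
iteration count, and the four condition values per case — the same report
the batch CLI writes as a manifest.
"""
from arcplan.suite import run_suite

cases = run_suite(base_seed=1, n_cases=3)
print("seed  status      it  V78Gy(PTV1)  D2%(body)  V72Gy(PTV2)  D1%(urethra)")
for case in cases:
    i = case.result.indices
    print(
        f"{case.seed:4d}  {case.result.status:10s} {case.result.iterations:3d}"
        f"  {i['PTV1_V78Gy_pct']:10.1f}%  {i['body_D2pct_cGy']:8.0f}"
        f"  {i['PTV2_V72Gy_pct']:10.1f}%  {i['urethra_D1pct_cGy']:9.0f}"
    )
print("Every value must sit inside its condition band for a case to finish.")
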