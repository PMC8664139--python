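"""Plan reporting: index reports, DVH exports, batch manifests."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .autoplan import AutoplanResult
from .dvh import dvh_table
from .phantom import Phantom
from .template import save_template

__all__ = ["write_plan_outputs", "write_batch_manifest", "iteration_histogram"]


def write_plan_outputs(result: AutoplanResult, phantom: Phantom, outdir: str | Path) -> Path:
    """Persist one plan: dose grid, DVH CSV, index report, audit trail,
    terminal template.  Deterministic for a fixed (seed, template, config)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    np.save(outdir / "dose_cgy.npy", result.dose.array)
    np.save(outdir / "dose_normalized_cgy.npy", result.normalized_dose.array)
    dvh_table(result.normalized_dose, phantom).to_csv(outdir / "dvh.csv", index=False)

    report = {
        "status": result.status,
        "iterations": result.iterations,
        "normalization_scale": result.normalization_scale,
        "indices_pre_normalization": {k: float(v) for k, v in result.indices.items()},
        "indices_normalized": {k: float(v) for k, v in result.normalized_indices.items()},
        "failed_conditions": [asdict(f) for f in result.failed_conditions],
    }
    (outdir / "indices.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    pd.DataFrame(
        sorted(result.indices.items()), columns=["index", "value"]
    ).to_csv(outdir / "indices.csv", index=False)

    result.trail.to_jsonl(outdir / "audit_trail.jsonl")
    save_template(result.template, outdir / "final_template.yaml")
    return outdir


def write_batch_manifest(rows: list[dict], outdir: str | Path) -> pd.DataFrame:
    """Write the per-case outcome table and the iteration histogram data."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    ok = manifest[manifest["status"] == "fulfilled"]
    if len(ok):
        iteration_histogram(ok["iterations"].tolist()).to_csv(
            outdir / "iteration_histogram.csv", index=False
        )
    return manifest


def iteration_histogram(iterations: list[int]) -> pd.DataFrame:
    """Counts of cases per number of planning iterations."""
    counts = pd.Series(iterations).value_counts().sort_index()
    return pd.DataFrame({"iterations": counts.index, "cases": counts.values})
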