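"""Fixed-seed phantom suites: the package's stand-in for a patient cohort.

Provides the canonical 20-case suite used by the batch runner, the test
suite and the reproduction script, plus the fine-grid (1 mm) geometry case
with a spherical CTV used to verify the margin recipe.
"""

from __future__ import annotations

from dataclasses import dataclass

from .autoplan import AutoplanResult, ControllerConfig, run_autoplan
from .phantom import AnatomyParams, Phantom, VoxelGrid, generate_phantom
from .template import PlanTemplate, default_template

__all__ = ["run_suite", "fine_grid_phantom", "SuiteCase"]


@dataclass
class SuiteCase:
    seed: int
    phantom: Phantom
    result: AutoplanResult


def run_suite(
    base_seed: int = 1,
    n_cases: int = 20,
    template: PlanTemplate | None = None,
    config: ControllerConfig | None = None,
) -> list[SuiteCase]:
    """Run the automatic planner on ``n_cases`` phantoms (seeds base..base+n-1)."""
    template = template or default_template()
    cases = []
    for i in range(n_cases):
        seed = base_seed + i
        phantom = generate_phantom(seed)
        result = run_autoplan(phantom, template.copy(), config)
        cases.append(SuiteCase(seed=seed, phantom=phantom, result=result))
    return cases


def fine_grid_phantom(seed: int = 1) -> Phantom:
    """A 1 mm-grid phantom with a spherical CTV for geometry verification.

    The anatomy is scaled down so the case fits a fine grid at desk scale;
    the margin recipe (8 mm, 5 mm posterior) is exactly resolvable at 1 mm.
    """
    grid = VoxelGrid.centered((96, 96, 64), 1.0)
    params = AnatomyParams(
        body_semi_x=(44.0, 44.0),
        body_semi_y=(40.0, 40.0),
        ctv_radius_x=(14.0, 14.0),
        ctv_radius_y=(14.0, 14.0),
        ctv_radius_z=(14.0, 14.0),
        ctv_center_y=(-6.0, -6.0),
        ctv_center_z=(0.0, 0.0),
        rectum_radius_x=(10.0, 10.0),
        rectum_radius_y=(7.0, 7.0),
        rectum_indent=(4.0, 4.0),
        bladder_radius_xy=(10.0, 10.0),
        bladder_radius_z=(10.0, 10.0),
        bladder_inset=(4.0, 4.0),
        urethra_radius=(3.0, 3.0),
        femoral_radius=(8.0, 8.0),
        femoral_center_x=(30.0, 30.0),
    )
    return generate_phantom(seed, grid=grid, params=params)
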