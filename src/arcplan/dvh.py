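"""Cumulative DVHs, scalar dose indices, HI/CI, and plan normalization.

Index conventions
-----------------
* ``V_x``: percent of a structure's volume receiving at least ``x`` cGy.
* ``D_y%``: minimum dose received by the hottest ``y``% of the volume,
  computed from the sorted voxel doses with linear interpolation between
  voxel ranks (never from binned curves, to avoid binning error).
* ``D_1cc``: dose to the hottest cubic centimetre.
* Heterogeneity index ``HI = D_1% / D_95%`` on PTV1.
* Conformity index ``CI = TV_PD^2 / (TV × V_PD)`` with ``TV`` the PTV1
  volume, ``TV_PD`` the PTV1 volume covered by the prescription dose and
  ``V_PD`` the total body volume enclosed by the prescription isodose.

Plans are normalized for reporting so that 95% of PTV1 receives the
prescription dose; the planning loop's conditions are checked on the raw
optimizer output (see :mod:`arcplan.autoplan`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import DoseDistribution
from .phantom import Phantom, StructureMask

__all__ = [
    "DVHCurve",
    "DVHError",
    "compute_dvh",
    "v_index",
    "d_index",
    "d_volume",
    "conformity_heterogeneity",
    "normalize_plan",
    "plan_indices",
    "dvh_table",
]


class DVHError(ValueError):
    """Invalid DVH computation request."""


def _struct_doses(dose: DoseDistribution | np.ndarray, mask: StructureMask) -> np.ndarray:
    arr = dose.array if isinstance(dose, DoseDistribution) else np.asarray(dose, dtype=float)
    if mask.is_empty():
        raise DVHError(f"structure {mask.name!r} is empty")
    return arr[mask.mask].astype(float)


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of volume receiving at least each bin dose."""

    structure: str
    dose_edges_cgy: np.ndarray  # uniform-width bin edges, starting at 0
    volume_percent: np.ndarray  # same length; 100% at 0 cGy, 0% above max

    def at(self, dose_cgy: float) -> float:
        """Curve value at an arbitrary dose via linear interpolation."""
        return float(np.interp(dose_cgy, self.dose_edges_cgy, self.volume_percent))


def compute_dvh(
    dose: DoseDistribution | np.ndarray, mask: StructureMask, bin_width_cgy: float = 10.0
) -> DVHCurve:
    """Cumulative DVH of a structure; exact at bin edges."""
    if bin_width_cgy <= 0:
        raise DVHError("bin width must be positive")
    d = _struct_doses(dose, mask)
    top = float(d.max())
    n_bins = int(np.floor(top / bin_width_cgy + 1e-9)) + 2
    edges = bin_width_cgy * np.arange(n_bins)
    # percent of voxels with dose >= edge
    vol = 100.0 * (1.0 - np.searchsorted(np.sort(d), edges, side="left") / d.size)
    return DVHCurve(mask.name, edges, vol)


def v_index(dose: DoseDistribution | np.ndarray, mask: StructureMask, x_cgy: float) -> float:
    """Percent of the structure receiving at least ``x_cgy``."""
    d = _struct_doses(dose, mask)
    return 100.0 * float(np.mean(d >= x_cgy))


def d_index(dose: DoseDistribution | np.ndarray, mask: StructureMask, y_percent: float) -> float:
    """Dose (cGy) received by the hottest ``y_percent`` of the structure."""
    if not (0 < y_percent <= 100):
        raise DVHError(f"y must be in (0, 100], got {y_percent}")
    d = _struct_doses(dose, mask)
    return float(np.quantile(d, 1.0 - y_percent / 100.0, method="linear"))


def d_volume(dose: DoseDistribution | np.ndarray, mask: StructureMask, v_cc: float) -> float:
    """Dose (cGy) to the hottest ``v_cc`` cm³ of the structure."""
    vol = mask.volume_cc
    if v_cc <= 0 or v_cc > vol:
        raise DVHError(f"volume {v_cc} cc outside (0, {vol:.2f}] for {mask.name!r}")
    return d_index(dose, mask, 100.0 * v_cc / vol)


def d_median(dose: DoseDistribution | np.ndarray, mask: StructureMask) -> float:
    return d_index(dose, mask, 50.0)


def conformity_heterogeneity(
    dose: DoseDistribution | np.ndarray,
    ptv1: StructureMask,
    body: StructureMask,
    prescription_cgy: float,
) -> tuple[float, float]:
    """Heterogeneity and conformity indices of a plan.

    ``HI = D_1%/D_95%`` on PTV1; ``CI = TV_PD² / (TV · V_PD)`` where volumes
    are in cc and the prescription isodose volume is taken within the body.
    """
    d95 = d_index(dose, ptv1, 95.0)
    if d95 == 0.0:
        warnings.warn("PTV1 D95% is zero; HI undefined (inf)", stacklevel=2)
        hi = float("inf")
    else:
        hi = d_index(dose, ptv1, 1.0) / d95
    arr = dose.array if isinstance(dose, DoseDistribution) else np.asarray(dose, dtype=float)
    vox_cc = ptv1.grid.voxel_volume_cc
    tv = ptv1.count * vox_cc
    tv_pd = int(np.sum(ptv1.mask & (arr >= prescription_cgy))) * vox_cc
    v_pd = int(np.sum(body.mask & (arr >= prescription_cgy))) * vox_cc
    if v_pd == 0:
        warnings.warn("prescription isodose volume is empty; CI set to 0", stacklevel=2)
        return hi, 0.0
    ci = tv_pd**2 / (tv * v_pd)
    return hi, ci


def normalize_plan(
    dose: DoseDistribution, ptv1: StructureMask, prescription_cgy: float
) -> tuple[DoseDistribution, float]:
    """Scale the dose so that 95% of PTV1 receives the prescription dose.

    Returns the scaled dose and the scale factor; applying the function
    twice is idempotent (the second factor is 1).
    """
    d95 = d_index(dose, ptv1, 95.0)
    if d95 <= 0:
        raise DVHError("PTV1 D95% is zero; cannot normalize")
    scale = prescription_cgy / d95
    return dose.scaled(scale), scale


def plan_indices(dose: DoseDistribution, phantom: Phantom, prescription_cgy: float = 7800.0) -> dict:
    """The standard scalar index report for one plan (keys are index names)."""
    idx: dict[str, float] = {}
    ptv1, ptv2 = phantom["PTV1"], phantom["PTV2"]
    body, urethra, rectum, bladder = (
        phantom["body"],
        phantom["urethra"],
        phantom["rectum"],
        phantom["bladder"],
    )
    idx["PTV1_V78Gy_pct"] = v_index(dose, ptv1, 7800.0)
    idx["PTV1_D1pct_cGy"] = d_index(dose, ptv1, 1.0)
    idx["PTV1_D2pct_cGy"] = d_index(dose, ptv1, 2.0)
    idx["PTV1_D95pct_cGy"] = d_index(dose, ptv1, 95.0)
    idx["PTV1_D98pct_cGy"] = d_index(dose, ptv1, 98.0)
    idx["PTV1_Dmedian_cGy"] = d_median(dose, ptv1)
    idx["PTV2_V72Gy_pct"] = v_index(dose, ptv2, 7200.0)
    idx["PTV2_D95pct_cGy"] = d_index(dose, ptv2, 95.0)
    idx["body_D2pct_cGy"] = d_index(dose, body, 2.0)
    idx["urethra_D1pct_cGy"] = d_index(dose, urethra, 1.0)
    idx["urethra_D2pct_cGy"] = d_index(dose, urethra, 2.0)
    for x in (70, 65, 40):
        idx[f"rectum_V{x}Gy_pct"] = v_index(dose, rectum, x * 100.0)
    for x in (70, 65, 45, 40):
        idx[f"bladder_V{x}Gy_pct"] = v_index(dose, bladder, x * 100.0)
    for side in ("L", "R"):
        fem = phantom[f"femoral_head_{side}"]
        v = min(1.0, fem.volume_cc)
        idx[f"femoral_head_{side}_D1cc_cGy"] = d_volume(dose, fem, v)
    hi, ci = conformity_heterogeneity(dose, ptv1, body, prescription_cgy)
    idx["HI"] = hi
    idx["CI"] = ci
    vox_cc = phantom.grid.voxel_volume_cc
    idx["TV_cc"] = ptv1.count * vox_cc
    idx["TV_PD_cc"] = int(np.sum(ptv1.mask & (dose.array >= prescription_cgy))) * vox_cc
    idx["V_PD_cc"] = int(np.sum(body.mask & (dose.array >= prescription_cgy))) * vox_cc
    return idx


def dvh_table(
    dose: DoseDistribution, phantom: Phantom, bin_width_cgy: float = 10.0
) -> pd.DataFrame:
    """Long-form DVH export: columns structure, dose_cGy, volume_percent."""
    frames = []
    for name, mask in phantom.structures().items():
        if mask.is_empty():
            continue
        curve = compute_dvh(dose, mask, bin_width_cgy)
        frames.append(
            pd.DataFrame(
                {
                    "structure": name,
                    "dose_cGy": curve.dose_edges_cgy,
                    "volume_percent": curve.volume_percent,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
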