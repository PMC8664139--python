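"""Synthetic pelvic phantoms and planning-structure geometry.

The phantom is a regular voxel grid carrying boolean occupancy masks for the
primary anatomy of a prostate case — body contour, CTV (prostate), rectum,
bladder, urethra and the two femoral heads — plus the derived planning
structures built from them by margin expansion and boolean algebra:

* ``PTV``     — CTV expanded by 8 mm in every direction except posteriorly,
  where a 5 mm margin is used (setup-error margin).
* ``PTV1``    — PTV minus the rectum (the part of the PTV prescribed 78 Gy).
* ``PTV2``    — PTV ∩ rectum overlap (prescribed 72 Gy).
* ``zRectum`` — planning helper: rectum expanded 5 mm posteriorly, minus the
  PTV expanded by a 3 mm buffer; used to shape the posterior dose gradient.

Axis convention (fixed): x = patient left (+), y = anterior (+) / posterior
(−), z = superior (+).  Coordinates are attached to voxel centers.

Margins are anisotropic and define an axis-aligned ellipsoidal neighborhood:
a voxel belongs to the expansion iff its center lies within the metric
``sum((delta_u / m_u)**2) <= 1`` of some source voxel center, where ``m_u``
is the margin for the sign of ``delta_u`` on that axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "VoxelGrid",
    "StructureMask",
    "Margins",
    "Phantom",
    "AnatomyParams",
    "PhantomError",
    "expand_margin",
    "subtract",
    "intersect",
    "build_derived_structures",
    "generate_phantom",
    "save_phantom",
    "load_phantom",
]

PRIMARY_NAMES = (
    "body",
    "CTV",
    "rectum",
    "bladder",
    "urethra",
    "femoral_head_L",
    "femoral_head_R",
)
DERIVED_NAMES = ("PTV", "PTV1", "PTV2", "zRectum")

#: Structures treated as targets when cost-function evaluation regions
#: retreat from the target (shrink margins).  The urethra is embedded in the
#: CTV and is prescribed target dose, so it counts as a target here.
TARGET_STRUCTURES = frozenset({"CTV", "PTV", "PTV1", "PTV2", "urethra"})


class PhantomError(ValueError):
    """Invalid phantom geometry or parameters."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel lattice with physical spacing and origin (all mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(int(n) < 1 for n in self.shape):
            raise PhantomError(f"grid shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise PhantomError(f"grid spacings must be positive, got {self.spacing}")

    @classmethod
    def centered(cls, shape: tuple[int, int, int], spacing: float | tuple) -> "VoxelGrid":
        """Grid whose voxel-center cloud is centered on the world origin."""
        if np.isscalar(spacing):
            spacing = (float(spacing),) * 3
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
        return cls(tuple(int(n) for n in shape), tuple(float(s) for s in spacing), origin)

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def coord_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (nx,1,1), (1,ny,1), (1,1,nz) center-coordinate arrays."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z


@dataclass
class StructureMask:
    """Named boolean occupancy mask on a :class:`VoxelGrid`."""

    name: str
    mask: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.grid.shape):
            raise PhantomError(
                f"mask {self.name!r} shape {self.mask.shape} != grid shape {self.grid.shape}"
            )

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cc(self) -> float:
        return self.count * self.grid.voxel_volume_cc

    def is_empty(self) -> bool:
        return not self.mask.any()

    def issubset(self, other: "StructureMask") -> bool:
        return bool(np.all(~self.mask | other.mask))


@dataclass(frozen=True)
class Margins:
    """Per-direction expansion margins in mm.

    ``y_minus`` is the posterior margin under the fixed axis convention.
    """

    x_plus: float
    x_minus: float
    y_plus: float
    y_minus: float
    z_plus: float
    z_minus: float

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.as_tuple()):
            raise PhantomError(f"margins must be non-negative, got {self}")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.x_plus, self.x_minus, self.y_plus, self.y_minus, self.z_plus, self.z_minus)

    @classmethod
    def isotropic(cls, m: float) -> "Margins":
        return cls(m, m, m, m, m, m)

    @classmethod
    def ctv_to_ptv(cls, all_mm: float = 8.0, posterior_mm: float = 5.0) -> "Margins":
        """The CTV→PTV recipe: uniform margin except a reduced posterior one."""
        return cls(all_mm, all_mm, all_mm, posterior_mm, all_mm, all_mm)

    @classmethod
    def posterior_only(cls, mm: float) -> "Margins":
        return cls(0.0, 0.0, 0.0, mm, 0.0, 0.0)


def _structuring_offsets(margins: Margins, spacing: tuple[float, float, float]) -> np.ndarray:
    """Boolean structuring element for the anisotropic ellipsoidal metric.

    Element ``[r + delta]`` is True iff a displacement of ``delta`` voxels
    lies inside the direction-dependent margin ellipsoid.  The array has odd
    extent on every axis with the zero displacement at its center.
    """
    m = margins.as_tuple()
    radii = []
    for ax in range(3):
        mx = max(m[2 * ax], m[2 * ax + 1])
        radii.append(int(np.floor(mx / spacing[ax] + 1e-9)))
    rx, ry, rz = radii
    dx = np.arange(-rx, rx + 1)[:, None, None] * spacing[0]
    dy = np.arange(-ry, ry + 1)[None, :, None] * spacing[1]
    dz = np.arange(-rz, rz + 1)[None, None, :] * spacing[2]

    def _term(delta: np.ndarray, m_plus: float, m_minus: float) -> np.ndarray:
        margin = np.where(delta >= 0, m_plus, m_minus)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(margin > 0, (delta / np.where(margin > 0, margin, 1.0)) ** 2, np.inf)
        return np.where(delta == 0, 0.0, t)

    metric = (
        _term(dx, margins.x_plus, margins.x_minus)
        + _term(dy, margins.y_plus, margins.y_minus)
        + _term(dz, margins.z_plus, margins.z_minus)
    )
    return metric <= 1.0 + 1e-9


def expand_margin(mask: StructureMask, margins: Margins) -> StructureMask:
    """Dilate a mask by anisotropic margins (axis-scaled ellipsoidal metric).

    The result is a superset of the input; with all margins zero it is the
    input unchanged.  Implemented as an FFT convolution with the structuring
    element followed by thresholding, which is exact for boolean masks.
    """
    if mask.is_empty():
        raise PhantomError(f"cannot expand empty mask {mask.name!r}")
    se = _structuring_offsets(margins, mask.grid.spacing)
    if se.shape == (1, 1, 1):
        return StructureMask(mask.name, mask.mask.copy(), mask.grid)
    conv = fftconvolve(mask.mask.astype(np.float32), se.astype(np.float32), mode="same")
    out = conv > 0.5
    out |= mask.mask  # guard against roundoff ever dropping a source voxel
    return StructureMask(mask.name, out, mask.grid)


def _check_same_grid(a: StructureMask, b: StructureMask) -> None:
    if a.grid != b.grid:
        raise PhantomError(f"masks {a.name!r} and {b.name!r} live on different grids")


def subtract(a: StructureMask, b: StructureMask, name: str | None = None) -> StructureMask:
    """Set difference ``a \\ b`` of two masks on the same grid."""
    _check_same_grid(a, b)
    return StructureMask(name or a.name, a.mask & ~b.mask, a.grid)


def intersect(a: StructureMask, b: StructureMask, name: str | None = None) -> StructureMask:
    """Set intersection of two masks on the same grid."""
    _check_same_grid(a, b)
    return StructureMask(name or a.name, a.mask & b.mask, a.grid)


@dataclass
class Phantom:
    """Voxelized pelvic phantom: grid, anatomy masks, relative density."""

    grid: VoxelGrid
    primaries: dict[str, StructureMask]
    derived: dict[str, StructureMask] = field(default_factory=dict)
    density: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = [n for n in PRIMARY_NAMES if n not in self.primaries]
        if missing:
            raise PhantomError(f"missing primary structures: {missing}")
        if self.density is None:
            # uniform water body by default
            self.density = self.primaries["body"].mask.astype(np.float32)

    def __getitem__(self, name: str) -> StructureMask:
        if name in self.primaries:
            return self.primaries[name]
        if name in self.derived:
            return self.derived[name]
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.primaries or name in self.derived

    def structures(self) -> dict[str, StructureMask]:
        return {**self.primaries, **self.derived}

    def validate(self) -> None:
        """Assert the structural invariants of a fully built phantom."""
        body = self.primaries["body"]
        for name in ("CTV", "rectum", "bladder", "urethra"):
            if self.primaries[name].is_empty():
                raise PhantomError(f"required structure {name!r} is empty")
            if not self.primaries[name].issubset(body):
                raise PhantomError(f"{name!r} is not contained in the body contour")
        if self.derived:
            ptv, ptv1, ptv2 = self.derived["PTV"], self.derived["PTV1"], self.derived["PTV2"]
            if not self.primaries["CTV"].issubset(ptv):
                raise PhantomError("CTV is not contained in PTV")
            if not ptv.issubset(body):
                raise PhantomError("PTV is not contained in the body contour")
            if np.any(ptv1.mask & ptv2.mask):
                raise PhantomError("PTV1 and PTV2 overlap")
            if not np.array_equal(ptv1.mask | ptv2.mask, ptv.mask):
                raise PhantomError("PTV1 and PTV2 do not partition PTV")


def build_derived_structures(
    phantom: Phantom,
    ptv_margin_mm: float = 8.0,
    ptv_posterior_margin_mm: float = 5.0,
    zrectum_posterior_margin_mm: float = 5.0,
    zrectum_subtract_margin_mm: float = 3.0,
    zrectum_subtract_base: str = "PTV",
) -> Phantom:
    """Derive PTV, PTV1, PTV2 and zRectum from the primary anatomy.

    ``zrectum_subtract_base`` selects whether the 3 mm buffer removed from
    the posteriorly-expanded rectum is grown from the whole PTV (default)
    or from PTV1 only; the two differ only inside the rectum overlap.
    """
    ctv = phantom.primaries["CTV"]
    rectum = phantom.primaries["rectum"]
    if ctv.is_empty() or rectum.is_empty():
        raise PhantomError("CTV and rectum must be non-empty to build derived structures")
    if zrectum_subtract_base not in ("PTV", "PTV1"):
        raise PhantomError(f"zrectum_subtract_base must be 'PTV' or 'PTV1', got {zrectum_subtract_base!r}")

    ptv = expand_margin(ctv, Margins.ctv_to_ptv(ptv_margin_mm, ptv_posterior_margin_mm))
    ptv = intersect(ptv, phantom.primaries["body"], name="PTV")
    ptv1 = subtract(ptv, rectum, name="PTV1")
    ptv2 = intersect(ptv, rectum, name="PTV2")

    zrect = expand_margin(rectum, Margins.posterior_only(zrectum_posterior_margin_mm))
    base = ptv if zrectum_subtract_base == "PTV" else ptv1
    buffer = expand_margin(base, Margins.isotropic(zrectum_subtract_margin_mm))
    zrect = subtract(zrect, buffer, name="zRectum")
    zrect = intersect(zrect, phantom.primaries["body"], name="zRectum")

    out = replace(phantom, derived={"PTV": ptv, "PTV1": ptv1, "PTV2": ptv2, "zRectum": zrect})
    out.validate()
    return out


@dataclass(frozen=True)
class AnatomyParams:
    """Uniform sampling ranges (mm) for the randomized phantom anatomy.

    Defaults describe a typical adult male pelvis at the scale of this
    surrogate: a prostate of ~2 cm radius abutting the rectum posteriorly,
    a bladder resting on the anterior-superior prostate surface, a urethra
    running through the gland (thickened so it spans ~100 voxels on the
    default 4 mm grid), and femoral heads lateral to the target.
    """

    body_semi_x: tuple[float, float] = (84.0, 92.0)
    body_semi_y: tuple[float, float] = (68.0, 76.0)
    ctv_radius_x: tuple[float, float] = (18.0, 24.0)
    ctv_radius_y: tuple[float, float] = (18.0, 24.0)
    ctv_radius_z: tuple[float, float] = (18.0, 24.0)
    ctv_center_y: tuple[float, float] = (-12.0, -2.0)
    ctv_center_z: tuple[float, float] = (-4.0, 4.0)
    # the rectum is an elliptical cylinder, wider laterally than
    # antero-posteriorly, as it flattens against the prostate
    rectum_radius_x: tuple[float, float] = (16.0, 20.0)
    rectum_radius_y: tuple[float, float] = (10.0, 14.0)
    # anterior reach of the rectum past the CTV posterior surface (mm);
    # positive values model the abutting contours interpenetrating, which
    # keeps the 5 mm posterior-margin overlap shell resolved on a 4 mm grid
    # (the coverage band needs a couple of voxels of slack inside PTV2)
    rectum_indent: tuple[float, float] = (4.0, 8.0)
    bladder_radius_xy: tuple[float, float] = (24.0, 30.0)
    bladder_radius_z: tuple[float, float] = (24.0, 30.0)
    bladder_inset: tuple[float, float] = (4.0, 8.0)  # overlap into the PTV margin shell
    urethra_radius: tuple[float, float] = (8.0, 9.0)
    femoral_radius: tuple[float, float] = (16.0, 20.0)
    femoral_center_x: tuple[float, float] = (50.0, 58.0)


def _ellipsoid(grid: VoxelGrid, center, radii) -> np.ndarray:
    x, y, z = grid.coord_arrays()
    cx, cy, cz = center
    rx, ry, rz = radii
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def _cylinder_z(grid: VoxelGrid, center_xy, radius_xy, z_lo, z_hi) -> np.ndarray:
    x, y, z = grid.coord_arrays()
    cx, cy = center_xy
    rx, ry = (radius_xy, radius_xy) if np.isscalar(radius_xy) else radius_xy
    inside = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0
    return inside & (z >= z_lo) & (z <= z_hi)


def generate_phantom(
    seed: int,
    grid: VoxelGrid | None = None,
    params: AnatomyParams | None = None,
    derive: bool = True,
) -> Phantom:
    """Generate a reproducible synthetic pelvic phantom.

    One integer ``seed`` drives every anatomical draw; identical arguments
    give bitwise-identical phantoms.  The default geometry guarantees a
    non-empty rectum/PTV overlap so that PTV2 exists.
    """
    grid = grid or VoxelGrid.centered((48, 48, 32), 4.0)
    params = params or AnatomyParams()
    rng = np.random.default_rng(seed)

    def draw(lo_hi):
        lo, hi = lo_hi
        return float(rng.uniform(lo, hi))

    bx, by = draw(params.body_semi_x), draw(params.body_semi_y)
    x, y, z = grid.coord_arrays()
    body = ((x / bx) ** 2 + (y / by) ** 2 <= 1.0) & np.ones_like(z, dtype=bool)

    crx, cry, crz = (draw(params.ctv_radius_x), draw(params.ctv_radius_y), draw(params.ctv_radius_z))
    cy_c, cz_c = draw(params.ctv_center_y), draw(params.ctv_center_z)
    ctv = _ellipsoid(grid, (0.0, cy_c, cz_c), (crx, cry, crz))

    r_rect_x, r_rect_y = draw(params.rectum_radius_x), draw(params.rectum_radius_y)
    indent = draw(params.rectum_indent)
    rect_cy = cy_c - cry + indent - r_rect_y
    z_lo, z_hi = grid.axis_coords(2)[0], grid.axis_coords(2)[-1]
    rectum = _cylinder_z(grid, (0.0, rect_cy), (r_rect_x, r_rect_y), z_lo, z_hi)

    br_xy, br_z = draw(params.bladder_radius_xy), draw(params.bladder_radius_z)
    inset = draw(params.bladder_inset)
    bl_cy = cy_c + cry + br_xy - inset
    bl_cz = cz_c + crz + br_z - inset
    bladder = _ellipsoid(grid, (0.0, bl_cy, bl_cz), (br_xy, br_xy, br_z))
    bladder &= ~ctv  # the bladder wall may dip into the PTV margin but not the gland

    u_r = draw(params.urethra_radius)
    urethra = _cylinder_z(grid, (0.0, cy_c), u_r, cz_c - 0.8 * crz, cz_c + 0.8 * crz)
    urethra &= ctv

    f_r = draw(params.femoral_radius)
    f_x = draw(params.femoral_center_x)
    fem_l = _ellipsoid(grid, (+f_x, cy_c, cz_c), (f_r, f_r, f_r))
    fem_r = _ellipsoid(grid, (-f_x, cy_c, cz_c), (f_r, f_r, f_r))

    masks = {
        "body": body,
        "CTV": ctv,
        "rectum": rectum & body,
        "bladder": bladder & body,
        "urethra": urethra,
        "femoral_head_L": fem_l & body,
        "femoral_head_R": fem_r & body,
    }
    for name, m in masks.items():
        if not m.any():
            raise PhantomError(
                f"anatomy parameters place no voxels for {name!r} inside the body/grid"
            )
    if not (ctv.sum() and np.all(~ctv | body)):
        raise PhantomError("CTV does not fit inside the body contour")

    primaries = {n: StructureMask(n, m, grid) for n, m in masks.items()}
    phantom = Phantom(grid=grid, primaries=primaries, seed=seed)
    if derive:
        phantom = build_derived_structures(phantom)
        phantom.validate()
    return phantom


def surface_margin_mm(
    phantom: Phantom, inner: str = "CTV", outer: str = "PTV", axis: int = 0, sign: int = +1
) -> float:
    """Distance between two nested structure surfaces along one axis.

    Measured along the grid line through the inner structure's centroid, as
    the offset between the outermost occupied voxels of ``inner`` and
    ``outer`` in the given direction (``sign`` = +1 or -1), in mm.  On a fine
    grid this recovers the expansion margin (e.g. the CTV→PTV recipe).
    """
    inner_mask = phantom[inner].mask
    outer_mask = phantom[outer].mask
    centroid = np.round(np.argwhere(inner_mask).mean(axis=0)).astype(int)
    sel: list = list(centroid)
    sel[axis] = slice(None)
    line_in = np.flatnonzero(inner_mask[tuple(sel)])
    line_out = np.flatnonzero(outer_mask[tuple(sel)])
    if line_in.size == 0 or line_out.size == 0:
        raise PhantomError("structures do not intersect the centroid line")
    if sign >= 0:
        steps = line_out.max() - line_in.max()
    else:
        steps = line_in.min() - line_out.min()
    return float(steps) * phantom.grid.spacing[axis]


# ---------------------------------------------------------------------------
# Serialization: one raster file per structure plus a JSON manifest.


def save_phantom(phantom: Phantom, directory: str | Path) -> Path:
    """Write each structure mask as an NRRD raster plus ``manifest.json``."""
    import SimpleITK as sitk

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for name, sm in phantom.structures().items():
        img = sitk.GetImageFromArray(sm.mask.astype(np.uint8).transpose(2, 1, 0))
        img.SetSpacing(tuple(float(s) for s in phantom.grid.spacing))
        img.SetOrigin(tuple(float(o) for o in phantom.grid.origin))
        sitk.WriteImage(img, str(directory / f"{name}.nrrd"), useCompression=True)
        names.append(name)
    manifest = {
        "grid": {
            "shape": list(phantom.grid.shape),
            "spacing": list(phantom.grid.spacing),
            "origin": list(phantom.grid.origin),
        },
        "seed": phantom.seed,
        "structures": names,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def load_phantom(directory: str | Path) -> Phantom:
    """Load a phantom written by :func:`save_phantom`."""
    import SimpleITK as sitk

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    g = manifest["grid"]
    grid = VoxelGrid(tuple(g["shape"]), tuple(g["spacing"]), tuple(g["origin"]))
    masks = {}
    for name in manifest["structures"]:
        arr = sitk.GetArrayFromImage(sitk.ReadImage(str(directory / f"{name}.nrrd")))
        masks[name] = StructureMask(name, arr.transpose(2, 1, 0).astype(bool), grid)
    primaries = {n: masks[n] for n in PRIMARY_NAMES}
    derived = {n: masks[n] for n in DERIVED_NAMES if n in masks}
    return Phantom(grid=grid, primaries=primaries, derived=derived, seed=manifest.get("seed"))
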