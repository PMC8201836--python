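"""Seeded synthetic pelvic phantoms.

Every downstream stage of the toolkit (rod generation, dose optimisation,
DVH evaluation) is exercised on deterministic voxel phantoms that emulate the
relative pelvic geometry of a cervix boost case: a clinical target volume
(CTV) of 30-90 cm3 modelled as a super-ellipsoid bent along z (the uterine
curvature gives the spline rods something to follow), with the bladder
anterior, rectum and sigmoid posterior and the bowel bag superior.  Only the
relative geometry matters to the planning method; no CT intensities are
simulated.

DICOM patient axes: +y is posterior, so "anterior of the CTV" means a smaller
y centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import StructureMask, StructureSet, VoxelGrid
from .rods import expand

__all__ = ["PhantomSpec", "generate_phantom", "generate_cohort", "OAR_NAMES"]

OAR_NAMES = ("bladder", "rectum", "sigmoid", "bowel")

# Fixed phantom stage in mm; large enough for the 89 cm3 upper end of the
# CTV volume range plus all OARs and the surrounding dose bath.
_EXTENT_MM = (130.0, 150.0, 145.0)
_CTV_CENTER_MM = (65.0, 78.0, 58.0)
# CTV super-ellipsoid: semi-axis ratios (x, y, z) and shape exponent.
_CTV_AXIS_RATIOS = np.array([1.0, 0.80, 1.60])
_CTV_EXPONENT = 2.2


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic pelvic phantom.

    ``ctv_volume_cm3`` defaults to the 51 cm3 cohort median; volumes are
    expected in the 30-90 cm3 range.  ``oar_gap_mm`` is the minimum surface
    gap enforced between the CTV and every OAR.  ``spacing_mm`` defaults to
    1.25 mm so that a 5 mm rod spans four voxels; 2.5 mm is available for
    coarse, fast runs.
    """

    seed: int = 0
    ctv_volume_cm3: float = 51.0
    ctv_bend_angle_deg: float = 20.0
    oar_gap_mm: float = 4.0
    spacing_mm: float = 1.25

    def __post_init__(self) -> None:
        if not self.ctv_volume_cm3 > 0:
            raise ValueError("ctv_volume_cm3 must be > 0")
        if self.oar_gap_mm < 0:
            raise ValueError("oar_gap_mm must be >= 0")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be > 0")


def _make_grid(spacing_mm: float) -> VoxelGrid:
    shape = tuple(int(round(e / spacing_mm)) for e in _EXTENT_MM)
    return VoxelGrid(shape=shape, spacing_mm=spacing_mm, origin_mm=(0.0, 0.0, 0.0))


def _ctv_mask(
    grid: VoxelGrid, semi_axes: np.ndarray, bend_angle_deg: float
) -> np.ndarray:
    """Super-ellipsoid bent anteriorly along +z by ``bend_angle_deg``."""
    x, y, z = grid.coordinate_grids()
    cx, cy, cz = _CTV_CENTER_MM
    a, b, c = semi_axes
    dz = z - cz
    # Quadratic anterior displacement of the cross-section center above the
    # mid-plane; slope at the superior tip equals tan(bend angle).
    k = np.tan(np.radians(bend_angle_deg)) / (2.0 * c)
    y_shift = -k * np.where(dz > 0, dz, 0.0) ** 2
    p = _CTV_EXPONENT
    lhs = (
        np.abs((x - cx) / a) ** p
        + np.abs((y - cy - y_shift) / b) ** p
        + np.abs(dz / c) ** p
    )
    return lhs <= 1.0


def _ellipsoid(grid: VoxelGrid, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    x, y, z = grid.coordinate_grids()
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _capped_cylinder_z(
    grid: VoxelGrid, center: np.ndarray, radius: float, half_len: float
) -> np.ndarray:
    x, y, z = grid.coordinate_grids()
    radial = (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius**2
    axial = np.abs(z - center[2]) <= half_len
    return radial & axial


def generate_phantom(spec: PhantomSpec) -> StructureSet:
    """Build a deterministic phantom structure set from ``spec``.

    Returns masks named ``CTV``, ``bladder``, ``rectum``, ``sigmoid``,
    ``bowel`` on one grid.  The CTV volume is matched to the requested value
    within 5%; OARs are placed at anatomical offsets with seeded jitter and
    are carved to keep at least ``oar_gap_mm`` clearance from the CTV and to
    be pairwise disjoint.
    """
    grid = _make_grid(spec.spacing_mm)
    rng = np.random.default_rng(spec.seed)

    # --- CTV: solve the super-ellipsoid scale for the requested volume.
    axis_jitter = 1.0 + 0.05 * rng.uniform(-1, 1, size=3)
    ratios = _CTV_AXIS_RATIOS * axis_jitter
    bend = spec.ctv_bend_angle_deg * (1.0 + 0.1 * rng.uniform(-1, 1))
    target_mm3 = spec.ctv_volume_cm3 * 1000.0
    # start from the sphere-equivalent scale; volume ~ s^3, so a few
    # multiplicative corrections converge quickly
    s = (target_mm3 / (4.19 * np.prod(ratios))) ** (1.0 / 3.0)
    ctv_arr = None
    for _ in range(4):
        semi = ratios * s
        cx, cy, cz = _CTV_CENTER_MM
        if (
            cx - semi[0] < 0
            or cx + semi[0] > _EXTENT_MM[0]
            or cy - semi[1] < 0
            or cy + semi[1] > _EXTENT_MM[1]
            or cz - semi[2] < 0
            or cz + semi[2] > _EXTENT_MM[2]
        ):
            raise ValueError(
                f"requested CTV volume {spec.ctv_volume_cm3} cm3 is unreachable: "
                f"semi-axes {np.round(semi, 1)} mm exceed the phantom extent "
                f"{_EXTENT_MM} mm"
            )
        ctv_arr = _ctv_mask(grid, semi, bend)
        vol = ctv_arr.sum() * grid.voxel_volume_mm3
        if vol == 0:
            raise ValueError(
                f"requested CTV volume {spec.ctv_volume_cm3} cm3 is unreachable "
                f"at spacing {spec.spacing_mm} mm (voxelized volume is zero)"
            )
        s *= (target_mm3 / vol) ** (1.0 / 3.0)
    ctv = StructureMask("CTV", grid, ctv_arr)
    if abs(ctv.volume_cm3 - spec.ctv_volume_cm3) > 0.05 * spec.ctv_volume_cm3:
        raise ValueError(
            f"CTV volume {ctv.volume_cm3:.2f} cm3 deviates more than 5% from the "
            f"requested {spec.ctv_volume_cm3} cm3 (grid spacing too coarse)"
        )

    center = np.array(_CTV_CENTER_MM)
    a, b, c = ratios * s

    def jitter(scale_mm: float = 2.0) -> np.ndarray:
        return rng.uniform(-scale_mm, scale_mm, size=3)

    gap = spec.oar_gap_mm
    oar_arrays: dict[str, np.ndarray] = {}

    # Bladder: ellipsoid anterior (smaller y), slightly inferior.
    blad_semi = np.array([28.0, 21.0, 24.0]) * (1.0 + 0.1 * rng.uniform(-1, 1))
    blad_center = center + np.array([0.0, -(b + gap + blad_semi[1]), -10.0]) + jitter()
    oar_arrays["bladder"] = _ellipsoid(grid, blad_center, blad_semi)

    # Rectum: capped cylinder along z, posterior (larger y).
    rect_r = 12.0 * (1.0 + 0.1 * rng.uniform(-1, 1))
    rect_center = center + np.array([0.0, b + gap + rect_r, -15.0]) + jitter()
    oar_arrays["rectum"] = _capped_cylinder_z(grid, rect_center, rect_r, 45.0)

    # Sigmoid: narrower cylinder posterior-superior, offset laterally.
    sig_r = 9.0 * (1.0 + 0.1 * rng.uniform(-1, 1))
    sig_center = center + np.array([12.0, b + gap + sig_r + 4.0, 38.0]) + jitter()
    oar_arrays["sigmoid"] = _capped_cylinder_z(grid, sig_center, sig_r, 28.0)

    # Bowel bag: wide flat ellipsoid superior.
    bowel_semi = np.array([42.0, 30.0, 16.0]) * (1.0 + 0.1 * rng.uniform(-1, 1))
    bowel_center = center + np.array([0.0, -8.0, c + gap + bowel_semi[2]]) + jitter()
    oar_arrays["bowel"] = _ellipsoid(grid, bowel_center, bowel_semi)

    # Enforce CTV clearance and pairwise OAR disjointness.
    keep_out = expand(ctv, gap).data if gap > 0 else ctv.data
    structures = StructureSet(grid)
    structures.add(ctv)
    taken = keep_out.copy()
    for name in OAR_NAMES:
        arr = oar_arrays[name] & ~taken
        if not arr.any():
            raise ValueError(f"OAR '{name}' vanished after clearance carving")
        taken |= arr
        structures.add(StructureMask(name, grid, arr))
    return structures


def generate_cohort(n: int, base_seed: int) -> list[StructureSet]:
    """``n`` phantoms with distinct seeds and CTV volumes sampled in [30, 90] cm3.

    Member ``i`` uses ``PhantomSpec(seed=base_seed + i)`` with a volume drawn
    deterministically from ``base_seed``, so two cohorts with the same base
    seed are identical.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    specs = cohort_specs(n, base_seed)
    return [generate_phantom(spec) for spec in specs]


def cohort_specs(n: int, base_seed: int) -> list[PhantomSpec]:
    """The phantom specs :func:`generate_cohort` builds, for inspection/reuse."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    rng = np.random.default_rng(base_seed)
    volumes = rng.uniform(30.0, 90.0, size=n)
    return [
        PhantomSpec(seed=base_seed + i, ctv_volume_cm3=float(v))
        for i, v in enumerate(volumes)
    ]
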