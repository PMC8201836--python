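"""Virtual rod structures for spatially fractionated boost planning.

Rods are tubular sub-structures generated inside a target volume and used as
high-dose "seeds" during optimisation.  Two flavours exist:

* straight, parallel rods on a square planar lattice (free parameters:
  diameter, center-to-center pitch, in-plane offset, and the rod-axis tilt
  angles in the ZX and ZY planes of the DICOM patient system), clipped to
  the target; and
* a single "bending" rod: a natural cubic spline through two or more seed
  points, swept with a sphere to form a tube, for targets whose anatomy
  (e.g. a curved uterus) a straight rod follows poorly.

The module also provides Euclidean margin expansion and the valley/"cooling"
structure (target minus margin-expanded rods) that the peak-and-valley
strategy constrains.

Voxelization rule throughout: a voxel belongs to a structure iff its center
lies inside the continuous shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .core import StructureMask, VoxelGrid

__all__ = [
    "StraightRodGridSpec",
    "BendingRodSpec",
    "RodSet",
    "axis_from_angles",
    "generate_straight_rods",
    "generate_bending_rod",
    "bending_rod_centerline",
    "expand",
    "make_valley",
]


@dataclass(frozen=True)
class StraightRodGridSpec:
    """Square lattice of parallel cylindrical rods.

    Defaults follow the clinical template: 5.0 mm diameter, 15.0 mm
    center-to-center separation (leaving a 10 mm edge-to-edge gap) and at most
    three rods, one of them the most central.
    """

    diameter_mm: float = 5.0
    center_to_center_mm: float = 15.0
    offset_uv_mm: tuple[float, float] = (0.0, 0.0)
    angle_zx_deg: float = 0.0
    angle_zy_deg: float = 0.0
    max_rods: int | None = 3

    def __post_init__(self) -> None:
        if not self.diameter_mm > 0:
            raise ValueError("diameter_mm must be > 0")
        if self.center_to_center_mm <= self.diameter_mm:
            raise ValueError(
                f"center_to_center_mm ({self.center_to_center_mm}) must exceed "
                f"diameter_mm ({self.diameter_mm}); rods must not merge"
            )
        if self.max_rods is not None and self.max_rods < 1:
            raise ValueError("max_rods must be >= 1 when set")

    def validate_for_grid(self, grid: VoxelGrid) -> None:
        if self.diameter_mm < 2 * grid.spacing_mm:
            raise ValueError(
                f"diameter_mm ({self.diameter_mm}) must be at least two voxels "
                f"({2 * grid.spacing_mm} mm) for a faithful voxelization"
            )


@dataclass(frozen=True)
class BendingRodSpec:
    """Spline-bent tube through ordered seed points (patient mm coordinates)."""

    seed_points_mm: tuple[tuple[float, float, float], ...]
    diameter_mm: float = 5.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.seed_points_mm, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("seed_points_mm must be >= 2 points of 3 coordinates")
        if not self.diameter_mm > 0:
            raise ValueError("diameter_mm must be > 0")
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() == 0:
            raise ValueError("seed points must be pairwise distinct")

    @property
    def points(self) -> np.ndarray:
        return np.asarray(self.seed_points_mm, dtype=float)


@dataclass
class RodSet:
    """Labeled per-rod masks plus their union, sorted most-central-first."""

    rods: list[StructureMask] = field(default_factory=list)
    axis: np.ndarray | None = None
    dose_levels_gy: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rods)

    def __iter__(self):
        return iter(self.rods)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rods]

    def union_mask(self, grid: VoxelGrid | None = None) -> StructureMask:
        if not self.rods:
            if grid is None:
                raise ValueError("empty RodSet needs an explicit grid for its union")
            return StructureMask("rods", grid, np.zeros(grid.shape, dtype=bool))
        data = np.zeros(self.rods[0].grid.shape, dtype=bool)
        for r in self.rods:
            data |= r.data
        return StructureMask("rods", self.rods[0].grid, data)

    @property
    def volume_cm3(self) -> float:
        return self.union_mask().volume_cm3 if self.rods else 0.0


def axis_from_angles(angle_zx_deg: float, angle_zy_deg: float) -> np.ndarray:
    """Unit rod-axis vector from tilt angles in the ZX and ZY planes.

    Convention: start from +z, rotate by ``angle_zx_deg`` about the y axis
    (tilt in the ZX plane), then by ``angle_zy_deg`` about the x axis (tilt in
    the ZY plane).  (0, 0) maps to +z.  Angles must lie strictly inside
    (-90, 90) degrees — at 90 the rod would be parallel to the axial plane.
    """
    for name, ang in (("angle_zx_deg", angle_zx_deg), ("angle_zy_deg", angle_zy_deg)):
        if abs(ang) >= 90.0:
            raise ValueError(f"{name} must satisfy |angle| < 90, got {ang}")
    a = np.radians(angle_zx_deg)
    b = np.radians(angle_zy_deg)
    v = np.array([np.sin(a), 0.0, np.cos(a)])  # Ry(a) @ z
    rx = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, np.cos(b), -np.sin(b)],
            [0.0, np.sin(b), np.cos(b)],
        ]
    )
    v = rx @ v
    return v / np.linalg.norm(v)


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane unit vectors (u, v) perpendicular to the rod axis.

    For an untilted axis (+z) this is exactly (x, y), so lattice offsets are
    plain in-plane patient coordinates.
    """
    # u = y x axis is never degenerate here (|tilt| < 90 deg keeps axis_z > 0)
    u = np.cross([0.0, 1.0, 0.0], axis)
    u = u / np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def generate_straight_rods(
    target: StructureMask, spec: StraightRodGridSpec
) -> RodSet:
    """Voxelize the straight-rod lattice clipped to ``target``.

    The lattice lives in the plane perpendicular to the rod axis, anchored at
    the projection of the target centroid and translated by
    ``spec.offset_uv_mm``.  If ``spec.max_rods`` is set, the most central rod
    is always kept and the remaining slots go to the rods with the greatest
    within-target length; the result is sorted most-central-first.
    """
    if target.is_empty():
        raise ValueError("target structure is empty")
    spec.validate_for_grid(target.grid)
    grid = target.grid
    axis = axis_from_angles(spec.angle_zx_deg, spec.angle_zy_deg)
    u, v = _orthonormal_frame(axis)

    idx = np.argwhere(target.data)
    coords = np.asarray(grid.origin_mm) + grid.spacing_mm * idx
    rel = coords - target.centroid_mm()
    pu = rel @ u
    pv = rel @ v
    pw = rel @ axis

    pitch = spec.center_to_center_mm
    r2 = (spec.diameter_mm / 2.0) ** 2
    off_u, off_v = spec.offset_uv_mm

    iu = np.arange(np.floor((pu.min() - off_u) / pitch), np.ceil((pu.max() - off_u) / pitch) + 1)
    iv = np.arange(np.floor((pv.min() - off_v) / pitch), np.ceil((pv.max() - off_v) / pitch) + 1)

    candidates = []  # (centrality, length, center_uv, voxel index subset)
    for cu in off_u + pitch * iu:
        du2 = (pu - cu) ** 2
        if du2.min() > r2:
            continue
        for cv in off_v + pitch * iv:
            inside = du2 + (pv - cv) ** 2 <= r2
            if not inside.any():
                continue
            w = pw[inside]
            length = float(w.max() - w.min()) + grid.spacing_mm
            centrality = float(np.hypot(cu, cv))
            candidates.append((centrality, length, (cu, cv), idx[inside]))

    if not candidates:
        warnings.warn(
            "no rod lattice line intersects the target; returning an empty RodSet",
            stacklevel=2,
        )
        return RodSet(rods=[], axis=axis)

    candidates.sort(key=lambda c: c[0])
    if spec.max_rods is not None and len(candidates) > spec.max_rods:
        central = candidates[0]
        rest = sorted(candidates[1:], key=lambda c: -c[1])[: spec.max_rods - 1]
        candidates = sorted([central] + rest, key=lambda c: c[0])

    rods = []
    for i, (_, _, _, vox) in enumerate(candidates, start=1):
        data = np.zeros(grid.shape, dtype=bool)
        data[tuple(vox.T)] = True
        rods.append(StructureMask(f"rod_{i}", grid, data))
    return RodSet(rods=rods, axis=axis)


def generate_bending_rod(
    target: StructureMask, spec: BendingRodSpec
) -> StructureMask:
    """Tube swept along a natural cubic spline through the seed points.

    The spline is parameterised by chord length, densely resampled to uniform
    arc length, and swept with a sphere of ``spec.diameter_mm``; the tube is
    clipped to the target.  The first and last seed points must lie inside the
    target.  A centerline whose curvature radius falls below the tube radius
    triggers a warning (the overlapping volume is simply not double-counted,
    since the mask is a set).
    """
    grid = target.grid
    pts = spec.points
    for which, p in (("first", pts[0]), ("last", pts[-1])):
        iv = np.round((p - np.asarray(grid.origin_mm)) / grid.spacing_mm).astype(int)
        if (iv < 0).any() or (iv >= np.asarray(grid.shape)).any() or not target.data[tuple(iv)]:
            raise ValueError(
                f"{which} seed point {p} lies outside the target structure"
            )

    samples = bending_rod_centerline(spec, grid.spacing_mm)

    chord = np.concatenate(([0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))))
    spline = CubicSpline(chord, pts, bc_type="natural")
    t_dense = np.linspace(0.0, chord[-1], 4 * len(samples))
    d1 = spline(t_dense, 1)
    d2 = spline(t_dense, 2)
    speed = np.linalg.norm(d1, axis=1)
    cross = np.linalg.norm(np.cross(d1, d2), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        curvature = np.where(speed > 0, cross / speed**3, 0.0)
    kmax = float(np.nanmax(curvature))
    if kmax > 0 and 1.0 / kmax < spec.diameter_mm / 2.0:
        warnings.warn(
            f"centerline curvature radius {1.0 / kmax:.1f} mm is below the tube "
            f"radius {spec.diameter_mm / 2.0:.1f} mm; the tube self-overlaps",
            stacklevel=2,
        )

    # Voxels within the tube radius of the sampled centerline, within the
    # bounding box of the curve padded by one radius.
    radius = spec.diameter_mm / 2.0
    origin = np.asarray(grid.origin_mm)
    lo = np.clip(
        np.floor((samples.min(axis=0) - radius - origin) / grid.spacing_mm).astype(int),
        0,
        None,
    )
    hi = np.minimum(
        np.ceil((samples.max(axis=0) + radius - origin) / grid.spacing_mm).astype(int) + 1,
        np.asarray(grid.shape),
    )
    axes = [origin[k] + grid.spacing_mm * np.arange(lo[k], hi[k]) for k in range(3)]
    bx, by, bz = np.meshgrid(*axes, indexing="ij")
    box_pts = np.column_stack([bx.ravel(), by.ravel(), bz.ravel()])
    tree = cKDTree(samples)
    dist, _ = tree.query(box_pts, k=1)
    inside = (dist <= radius).reshape(bx.shape)

    data = np.zeros(grid.shape, dtype=bool)
    data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = inside
    data &= target.data
    return StructureMask("bending_rod", grid, data)


def bending_rod_centerline(spec: BendingRodSpec, spacing_mm: float) -> np.ndarray:
    """Arc-length-uniform samples of the natural cubic spline centerline.

    The spline is parameterised by chord length through the seed points and
    resampled at roughly a quarter of ``spacing_mm``; it passes exactly
    through every seed point.
    """
    pts = spec.points
    chord = np.concatenate(
        ([0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    )
    spline = CubicSpline(chord, pts, bc_type="natural")
    step = spacing_mm / 4.0
    t_dense = np.linspace(0.0, chord[-1], max(int(np.ceil(chord[-1] / step)) * 4, 8))
    dense = spline(t_dense)
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate(([0.0], np.cumsum(seg)))
    n_samples = max(int(np.ceil(arc[-1] / step)), 2)
    s_targets = np.linspace(0.0, arc[-1], n_samples + 1)
    samples = np.empty((n_samples + 1, 3))
    for k in range(3):
        samples[:, k] = np.interp(s_targets, arc, dense[:, k])
    return samples


def expand(mask: StructureMask, margin_mm: float) -> StructureMask:
    """Euclidean isotropic dilation by ``margin_mm``.

    A voxel is included iff its center lies within ``margin_mm`` of the input
    structure (distances between voxel centers); margin 0 is the identity.
    Used for PTV expansions (2 and 5 mm) and the valley margin.
    """
    if margin_mm < 0:
        raise ValueError(f"margin_mm must be >= 0, got {margin_mm}")
    if margin_mm == 0 or mask.is_empty():
        return StructureMask(mask.name, mask.grid, mask.data.copy())
    dist = ndimage.distance_transform_edt(
        ~mask.data, sampling=[mask.grid.spacing_mm] * 3
    )
    return StructureMask(mask.name, mask.grid, dist <= margin_mm + 1e-9)


def make_valley(
    target: StructureMask, rods: RodSet, margin_mm: float = 3.0
) -> StructureMask:
    """Valley ("cooling") structure: target minus the margin-expanded rods."""
    grid = target.grid
    union = rods.union_mask(grid)
    if not (union.data & ~target.data).sum() == 0:
        raise ValueError("rods extend outside the target; clip them first")
    grown = expand(union, margin_mm) if len(rods) else union
    data = target.data & ~grown.data
    if len(rods) and not data.any():
        warnings.warn(
            f"valley margin {margin_mm} mm leaves an empty valley", stacklevel=2
        )
    return StructureMask("valley", grid, data)
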