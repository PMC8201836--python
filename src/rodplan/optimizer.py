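"""Surrogate deliverable-dose optimizer.

This module deliberately does NOT model a clinical treatment planning system
(arc sequencing, MLC apertures, beam commissioning, transport-based dose
calculation are all out of scope).  It is a physically plausible surrogate:
the dose is a nonnegative intensity field convolved with an isotropic
Gaussian kernel — the kernel width (default sigma 3 mm, roughly a photon
penumbra at depth) forbids unphysically sharp dose and makes the 5 mm-rod /
10 mm-gap peak-and-valley pattern genuinely nontrivial to achieve.  The
intensity is fitted by fixed-step projected gradient descent on weighted
quadratic penalties:

* rod voxels below the rod minimum dose (SFRT_1 and SFRT_2),
* valley voxels above the valley maximum (SFRT_1 only),
* target voxels below the prescription (all strategies),
* a near-maximum (hottest-2 cm3) overdose penalty per organ at risk, and
* a dose-bath decay penalty outside the target plus 20 mm.

The result is returned un-normalized; prescription scaling is the job of
``dvh.normalize_to_d90``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import DoseGrid, StructureMask, StructureSet
from .rods import RodSet, expand

__all__ = [
    "STRATEGIES",
    "OptimizerConfig",
    "OptimizationResult",
    "optimize",
    "smooth_field",
]

STRATEGIES = ("SFRT_1", "SFRT_2", "SBRT")

#: Default hottest-2cm3 limits (Gy) used as optimizer penalties; these are the
#: hard upper limits of the shipped constraint table.
DEFAULT_OAR_LIMITS: Mapping[str, float] = {
    "bladder": 27.5,
    "rectum": 19.45,
    "sigmoid": 21.65,
    "bowel": 19.45,
}

DEFAULT_WEIGHTS: Mapping[str, float] = {
    "coverage": 1.0,  # target voxels below prescription
    "rod": 1.5,  # rod voxels below rod_min_gy
    "valley": 0.7,  # valley voxels above valley_max_gy (SFRT_1)
    "oar": 3.0,  # hottest-2cm3 OAR voxels above their limit
    "bath": 0.15,  # quadratic decay outside target + 20 mm
    "ptv": 1.0,  # optional extra coverage structure (mitigation strategy B)
}


@dataclass(frozen=True)
class OptimizerConfig:
    """Strategy, dose objectives and descent parameters of the surrogate.

    ``strategy`` selects which objectives are active: ``SFRT_1``
    (peak-and-valley: rod minimum + valley maximum), ``SFRT_2`` (peak-only:
    no valley/"negative" structure) or ``SBRT`` (uniform coverage; rods and
    valley are ignored).  ``rod_min_gy`` lives in the 60-80 Gy range;
    ``valley_max_gy`` defaults to 45 Gy; the prescription is 30 Gy over
    5 fractions.  ``ptv_coverage`` names an extra structure to receive the
    prescription (used by the re-optimisation mitigation strategy).
    """

    strategy: str = "SFRT_1"
    prescription_gy: float = 30.0
    rod_min_gy: float = 60.0
    valley_max_gy: float = 45.0
    kernel_sigma_mm: float = 3.0
    oar_limits: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OAR_LIMITS)
    )
    iterations: int = 300
    step_size: float = 2.0
    weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    ptv_coverage: str | None = None
    seed: int = 0  # reserved; the descent itself is deterministic

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"strategy must be one of {STRATEGIES}, got {self.strategy!r}"
            )
        if not self.kernel_sigma_mm > 0:
            raise ValueError("kernel_sigma_mm must be > 0")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if not 0 <= self.prescription_gy <= self.valley_max_gy < self.rod_min_gy:
            raise ValueError(
                "dose levels must satisfy prescription <= valley_max < rod_min, "
                f"got {self.prescription_gy}, {self.valley_max_gy}, {self.rod_min_gy}"
            )

    def with_(self, **kwargs) -> "OptimizerConfig":
        return replace(self, **kwargs)


@dataclass
class OptimizationResult:
    """Best-iterate dose plus the objective trace and a convergence flag."""

    dose: DoseGrid
    objective: np.ndarray
    converged: bool
    strategy: str


def smooth_field(
    intensity: np.ndarray, sigma_mm: float, grid_spacing_mm: float
) -> np.ndarray:
    """Mass-preserving isotropic Gaussian convolution of a nonnegative field.

    Linear and norm-non-increasing: the output maximum never exceeds the
    input maximum, and for a source away from the array boundary the total
    sum is preserved.
    """
    if not sigma_mm > 0:
        raise ValueError("sigma_mm must be > 0")
    return gaussian_filter(
        np.asarray(intensity, dtype=np.float64),
        sigma=sigma_mm / grid_spacing_mm,
        mode="constant",
        truncate=4.0,
    )


def _hottest_subset(dose_flat: np.ndarray, k: int) -> np.ndarray:
    """Indices (into dose_flat) of the k hottest voxels."""
    if k >= dose_flat.size:
        return np.arange(dose_flat.size)
    return np.argpartition(dose_flat, -k)[-k:]


def optimize(
    structures: StructureSet,
    rods: RodSet | None,
    valley: StructureMask | None,
    config: OptimizerConfig,
) -> OptimizationResult:
    """Fit the surrogate dose for one strategy.

    Preconditions: all structures share one grid; SFRT_1 requires rods and a
    valley mask; SFRT_2 requires rods; SBRT ignores both.  The intensity is
    initialised uniform (at the prescription) inside the target expanded by
    5 mm; with ``iterations == 0`` the returned dose is identically zero (the
    warm start counts as part of the first iteration).  The descent is
    deterministic for a fixed config.  If the objective has not decreased
    over the last 10% of iterations a non-convergence warning is emitted and
    the best iterate is returned anyway.
    """
    grid = structures.grid
    structures.require(["CTV"])
    ctv = structures["CTV"]
    if config.strategy in ("SFRT_1", "SFRT_2") and (rods is None or len(rods) == 0):
        raise ValueError(f"strategy {config.strategy} requires a non-empty RodSet")
    if config.strategy == "SFRT_1" and valley is None:
        raise ValueError("strategy SFRT_1 requires a valley mask")

    if config.iterations == 0:
        return OptimizationResult(
            dose=DoseGrid(grid, np.zeros(grid.shape)),
            objective=np.array([]),
            converged=True,
            strategy=config.strategy,
        )

    w = {**DEFAULT_WEIGHTS, **dict(config.weights)}
    sigma_vox = config.kernel_sigma_mm / grid.spacing_mm

    def smooth(a: np.ndarray) -> np.ndarray:
        return gaussian_filter(a, sigma=sigma_vox, mode="constant", truncate=4.0)

    ctv_m = ctv.data
    cover_masks: list[tuple[np.ndarray, float, float]] = [
        (ctv_m, config.prescription_gy, w["coverage"] / ctv_m.sum())
    ]
    if config.ptv_coverage is not None:
        structures.require([config.ptv_coverage])
        ptv_m = structures[config.ptv_coverage].data
        cover_masks.append((ptv_m, config.prescription_gy, w["ptv"] / ptv_m.sum()))

    use_rods = config.strategy in ("SFRT_1", "SFRT_2")
    rod_m = rods.union_mask(grid).data if use_rods else None
    valley_m = valley.data if (config.strategy == "SFRT_1" and valley is not None) else None
    if valley_m is not None and rod_m is not None and (valley_m & rod_m).any():
        raise ValueError("valley mask overlaps the rods")

    oar_entries = []
    k_2cm3 = max(int(round(2000.0 / grid.voxel_volume_mm3)), 1)
    for name, limit in config.oar_limits.items():
        if name in structures:
            flat_idx = np.flatnonzero(structures[name].data.ravel())
            if flat_idx.size:
                oar_entries.append((name, flat_idx, float(limit)))

    bath_m = ~expand(ctv, 20.0).data
    n_bath = max(int(bath_m.sum()), 1)

    x = np.where(expand(ctv, 5.0).data, config.prescription_gy, 0.0)

    objective = np.empty(config.iterations)
    best_obj = np.inf
    best_x = x
    eta = float(config.step_size)

    for it in range(config.iterations):
        dose = smooth(x)
        resid = np.zeros_like(dose)
        obj = 0.0

        for mask, level, weight in cover_masks:
            deficit = np.maximum(level - dose[mask], 0.0)
            obj += weight * float(deficit @ deficit)
            resid[mask] -= 2.0 * weight * deficit

        if rod_m is not None:
            weight = w["rod"] / rod_m.sum()
            deficit = np.maximum(config.rod_min_gy - dose[rod_m], 0.0)
            obj += weight * float(deficit @ deficit)
            resid[rod_m] -= 2.0 * weight * deficit

        if valley_m is not None and valley_m.any():
            weight = w["valley"] / valley_m.sum()
            excess = np.maximum(dose[valley_m] - config.valley_max_gy, 0.0)
            obj += weight * float(excess @ excess)
            resid[valley_m] += 2.0 * weight * excess

        dose_flat = dose.ravel()
        resid_flat = resid.ravel()
        for _, flat_idx, limit in oar_entries:
            hot = flat_idx[_hottest_subset(dose_flat[flat_idx], k_2cm3)]
            excess = np.maximum(dose_flat[hot] - limit, 0.0)
            weight = w["oar"] / hot.size
            obj += weight * float(excess @ excess)
            resid_flat[hot] += 2.0 * weight * excess

        bath_vals = dose[bath_m]
        weight = w["bath"] / n_bath
        obj += weight * float(bath_vals @ bath_vals)
        resid[bath_m] += 2.0 * weight * bath_vals

        objective[it] = obj
        if obj < best_obj:
            best_obj = obj
            best_x = x

        grad = smooth(resid)  # Gaussian kernel is self-adjoint
        gmax = np.abs(grad).max()
        if gmax == 0:
            objective = objective[: it + 1]
            break
        x = np.maximum(x - eta * grad / gmax, 0.0)

    tail = max(int(round(0.1 * objective.size)), 1)
    converged = objective.size <= tail or objective[-tail:].min() <= objective[
        : -tail
    ].min() or objective.size < config.iterations
    if not converged:
        warnings.warn(
            f"surrogate optimizer did not decrease the objective over the last "
            f"{tail} iterations (best {best_obj:.4g}, final {objective[-1]:.4g}); "
            "returning the best iterate",
            stacklevel=2,
        )

    return OptimizationResult(
        dose=DoseGrid(grid, smooth(best_x)),
        objective=objective,
        converged=bool(converged),
        strategy=config.strategy,
    )
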