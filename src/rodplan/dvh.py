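"""Cumulative dose-volume histograms and the scalar plan metrics.

Two routes to the scalar metrics exist deliberately:

* the binned cumulative DVH (default bin width 0.02 Gy) with linear
  interpolation between bin edges — the representation used for curves,
  average-DVH bands and prescription normalisation; and
* exact voxel-sort quantiles (:func:`voxel_dose_at_volume_pct`,
  :func:`voxel_dose_at_volume_cm3`) — strictly linear under a global dose
  scale, used by plan evaluation and mitigation where exact linearity matters.

The two agree within one bin width; this is property-tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DoseGrid, StructureMask

__all__ = [
    "DVHCurve",
    "AverageDVH",
    "MetricReport",
    "compute_dvh",
    "dose_at_volume_pct",
    "dose_at_volume_cm3",
    "volume_pct_at_dose",
    "voxel_dose_at_volume_pct",
    "voxel_dose_at_volume_cm3",
    "normalize_to_d90",
    "average_dvh",
]

DEFAULT_BIN_WIDTH_GY = 0.02


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of structure volume receiving >= each bin edge.

    ``cum_fraction[i]`` is the fraction of the structure receiving at least
    ``edges_gy[i]``; the curve starts at 1.0 at 0 Gy, is monotone
    non-increasing and ends at 0 one bin above the maximum dose.
    """

    structure: str
    volume_cm3: float
    bin_width_gy: float
    edges_gy: np.ndarray
    cum_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.edges_gy = np.asarray(self.edges_gy, dtype=float)
        self.cum_fraction = np.asarray(self.cum_fraction, dtype=float)
        if self.edges_gy.shape != self.cum_fraction.shape:
            raise ValueError("DVH edges and fractions differ in length")


@dataclass
class AverageDVH:
    """Per-bin mean of a set of DVH curves with 1 SD and 1.95 SD bands."""

    bin_width_gy: float
    edges_gy: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    band_1sd: tuple[np.ndarray, np.ndarray]
    band_195sd: tuple[np.ndarray, np.ndarray]
    n_curves: int


@dataclass
class MetricReport:
    """Scalar DVH metrics for one structure (doses in Gy, volumes in %)."""

    structure: str
    volume_cm3: float
    metrics: dict[str, float]

    def __getitem__(self, key: str) -> float:
        return self.metrics[key]


def compute_dvh(
    dose: DoseGrid,
    mask: StructureMask,
    bin_width_gy: float = DEFAULT_BIN_WIDTH_GY,
) -> DVHCurve:
    """Cumulative DVH of ``dose`` within ``mask`` on a fixed dose binning."""
    if mask.is_empty():
        raise ValueError(f"cannot compute DVH: structure '{mask.name}' is empty")
    if not bin_width_gy > 0:
        raise ValueError(f"bin width must be > 0, got {bin_width_gy}")
    doses = dose.values_in(mask)
    n = doses.size
    dmax = float(doses.max())
    n_bins = int(np.ceil(dmax / bin_width_gy)) + 1
    edges = bin_width_gy * np.arange(n_bins + 1)
    counts, _ = np.histogram(doses, bins=edges)
    # fraction receiving >= edge[i] == voxels falling in bins i..end
    tail = n - np.concatenate(([0], np.cumsum(counts)))
    return DVHCurve(
        structure=mask.name,
        volume_cm3=mask.volume_cm3,
        bin_width_gy=bin_width_gy,
        edges_gy=edges,
        cum_fraction=tail / n,
    )


def dose_at_volume_pct(dvh: DVHCurve, pct: float) -> float:
    """D_pct%: largest dose received by at least ``pct`` % of the structure.

    Linear interpolation between bin edges.
    """
    if not 0 < pct <= 100:
        raise ValueError(f"pct must be in (0, 100], got {pct}")
    f = pct / 100.0
    cum = dvh.cum_fraction
    above = np.nonzero(cum >= f)[0]
    if above.size == 0:  # only possible through float noise at f == 1
        return 0.0
    i = int(above[-1])
    if i == cum.size - 1:
        return float(dvh.edges_gy[-1])
    c0, c1 = cum[i], cum[i + 1]
    # c1 < f <= c0 here, so the denominator is positive
    return float(dvh.edges_gy[i] + dvh.bin_width_gy * (c0 - f) / (c0 - c1))


def dose_at_volume_cm3(dvh: DVHCurve, v_cm3: float) -> float:
    """D_vcm3: dose received by the hottest ``v_cm3`` of the structure."""
    if not 0 < v_cm3 <= dvh.volume_cm3:
        raise ValueError(
            f"queried volume {v_cm3} cm3 outside (0, {dvh.volume_cm3:.3f}] "
            f"for structure '{dvh.structure}'"
        )
    return dose_at_volume_pct(dvh, 100.0 * v_cm3 / dvh.volume_cm3)


def volume_pct_at_dose(dvh: DVHCurve, d_gy: float) -> float:
    """V_d: percent of the structure receiving at least ``d_gy``."""
    if d_gy < 0:
        raise ValueError(f"dose query must be >= 0, got {d_gy}")
    if d_gy >= dvh.edges_gy[-1]:
        return 0.0
    return 100.0 * float(np.interp(d_gy, dvh.edges_gy, dvh.cum_fraction))


def _voxel_quantile(doses: np.ndarray, hottest_fraction: float) -> float:
    """Dose received by at least the hottest ``hottest_fraction`` of voxels."""
    # quantile of the dose distribution at (1 - fraction), linear interpolation
    return float(np.quantile(doses, 1.0 - hottest_fraction))


def voxel_dose_at_volume_pct(dose: DoseGrid, mask: StructureMask, pct: float) -> float:
    """Exact (sort-based) D_pct%; strictly linear under global dose scaling."""
    if not 0 < pct <= 100:
        raise ValueError(f"pct must be in (0, 100], got {pct}")
    if mask.is_empty():
        raise ValueError(f"structure '{mask.name}' is empty")
    return _voxel_quantile(dose.values_in(mask), pct / 100.0)


def voxel_dose_at_volume_cm3(dose: DoseGrid, mask: StructureMask, v_cm3: float) -> float:
    """Exact (sort-based) D_vcm3 of the hottest ``v_cm3``."""
    vol = mask.volume_cm3
    if not 0 < v_cm3 <= vol:
        raise ValueError(
            f"queried volume {v_cm3} cm3 outside (0, {vol:.3f}] "
            f"for structure '{mask.name}'"
        )
    return voxel_dose_at_volume_pct(dose, mask, 100.0 * v_cm3 / vol)


def normalize_to_d90(
    dose: DoseGrid,
    ctv: StructureMask,
    target_gy: float = 30.0,
    bin_width_gy: float = DEFAULT_BIN_WIDTH_GY,
) -> tuple[DoseGrid, float]:
    """Scale the dose so that the CTV D90% (from the binned DVH) equals ``target_gy``.

    D90 is exactly linear in a global scale, but the binned estimate is only
    approximately so; the closed-form factor is therefore refined with a second
    pass.  Returns the scaled dose and the total scale factor applied.
    """
    if not dose.values_in(ctv).any():
        raise ValueError(f"zero dose in '{ctv.name}': cannot normalize coverage")
    factor = 1.0
    scaled = dose
    for _ in range(2):
        current = dose_at_volume_pct(compute_dvh(scaled, ctv, bin_width_gy), 90.0)
        if current <= 0:
            raise ValueError(f"D90% of '{ctv.name}' is zero: cannot normalize")
        step = target_gy / current
        factor *= step
        scaled = scaled.scaled(step)
    return scaled, factor


def average_dvh(curves: list[DVHCurve]) -> AverageDVH:
    """Mean DVH of >= 2 curves with 1 SD and 1.95 SD bands, clipped to [0, 1].

    Curves must share one bin width; shorter curves are extended with zeros
    (a cumulative DVH is identically 0 above its own maximum dose).  The SD is
    the per-bin sample standard deviation (n - 1).
    """
    if len(curves) < 2:
        raise ValueError("average DVH requires at least two curves")
    widths = {c.bin_width_gy for c in curves}
    if len(widths) != 1:
        raise ValueError(f"inconsistent DVH binning: bin widths {sorted(widths)}")
    bw = curves[0].bin_width_gy
    n_edges = max(c.edges_gy.size for c in curves)
    edges = bw * np.arange(n_edges)
    stack = np.zeros((len(curves), n_edges))
    for i, c in enumerate(curves):
        stack[i, : c.cum_fraction.size] = c.cum_fraction
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)

    def band(k: float) -> tuple[np.ndarray, np.ndarray]:
        return (np.clip(mean - k * sd, 0, 1), np.clip(mean + k * sd, 0, 1))

    return AverageDVH(
        bin_width_gy=bw,
        edges_gy=edges,
        mean=mean,
        sd=sd,
        band_1sd=band(1.0),
        band_195sd=band(1.95),
        n_curves=len(curves),
    )
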