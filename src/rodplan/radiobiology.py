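"""EQD2 conversion and cumulative dose arithmetic.

The linear-quadratic equivalent dose in 2 Gy fractions for a course of ``n``
fractions of ``d`` Gy each with tissue sensitivity ratio ``alpha/beta`` is

    EQD2 = n * d * (1 + d / (alpha/beta)) / (1 + 2 / (alpha/beta))

with the usual convention alpha/beta = 3 Gy for late-responding organs at risk
and 10 Gy for the tumour target.  The boost plans evaluated by this package are
summed with a previous, assumed-uniform external-beam course (default 45 Gy in
25 fractions) to yield cumulative EQD2 values comparable with brachytherapy
constraint tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "FractionationScheme",
    "PriorCourse",
    "eqd2",
    "eqd2_of_metric",
    "inverse_eqd2",
    "cumulative_eqd2",
    "ALPHA_BETA_TARGET",
    "ALPHA_BETA_OAR",
]

ALPHA_BETA_TARGET = 10.0  # Gy, tumour / CTV
ALPHA_BETA_OAR = 3.0  # Gy, late-responding normal tissue


@dataclass(frozen=True)
class FractionationScheme:
    """(n, d, alpha/beta): ``n`` fractions of ``d`` Gy with tissue ratio in Gy."""

    n: int
    d: float
    alpha_beta: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"fraction count n must be >= 1, got {self.n}")
        if self.d < 0:
            raise ValueError(f"dose per fraction d must be >= 0, got {self.d}")
        if not self.alpha_beta > 0:
            raise ValueError(f"alpha/beta must be > 0, got {self.alpha_beta}")

    @property
    def total_gy(self) -> float:
        return self.n * self.d


@dataclass(frozen=True)
class PriorCourse:
    """Previous uniform EBRT course summed into cumulative constraints.

    Defaults to 45 Gy in 25 fractions (1.8 Gy/fraction), the fractionation
    that is consistent with the shipped cumulative objective table; a
    2 Gy/fraction prior can be configured via ``n_fractions``.
    """

    total_gy: float = 45.0
    n_fractions: int = 25

    def scheme(self, alpha_beta: float) -> FractionationScheme:
        return FractionationScheme(
            self.n_fractions, self.total_gy / self.n_fractions, alpha_beta
        )

    def eqd2(self, alpha_beta: float) -> float:
        return eqd2(self.scheme(alpha_beta))


def eqd2(scheme: FractionationScheme) -> float:
    """EQD2 of a fractionation scheme, in Gy."""
    ab = scheme.alpha_beta
    return scheme.n * scheme.d * (1.0 + scheme.d / ab) / (1.0 + 2.0 / ab)


def eqd2_of_metric(total_dose_gy: float, n: int, alpha_beta: float) -> float:
    """EQD2 of a scalar DVH metric delivered as ``total_dose_gy`` over ``n`` fx.

    This is applied to scalar metrics (e.g. a D2cm3 value), assuming the metric
    dose is delivered in equal fractions; it is not a voxel-wise conversion.
    """
    if n < 1:
        raise ValueError(f"fraction count n must be >= 1, got {n}")
    if total_dose_gy < 0:
        raise ValueError(f"total dose must be >= 0, got {total_dose_gy}")
    return eqd2(FractionationScheme(n, total_dose_gy / n, alpha_beta))


def inverse_eqd2(target_eqd2_gy: float, n: int, alpha_beta: float) -> float:
    """Physical total dose over ``n`` fractions whose EQD2 equals the target.

    Solves the quadratic ``n*d*(1 + d/ab) / (1 + 2/ab) = target`` for the
    positive root in d and returns ``n*d``.  Round-trips with
    :func:`eqd2_of_metric` to ~1e-12 relative accuracy.
    """
    if n < 1:
        raise ValueError(f"fraction count n must be >= 1, got {n}")
    if target_eqd2_gy < 0:
        raise ValueError(f"target EQD2 must be >= 0, got {target_eqd2_gy}")
    if target_eqd2_gy == 0:
        return 0.0
    ab = alpha_beta
    # (n/ab) d^2 + n d - target (1 + 2/ab) = 0
    a = n / ab
    b = float(n)
    c = -target_eqd2_gy * (1.0 + 2.0 / ab)
    disc = b * b - 4.0 * a * c
    if disc < 0:  # unreachable for valid inputs (c <= 0)
        raise ValueError("no positive root for inverse EQD2")
    d = (-b + math.sqrt(disc)) / (2.0 * a)
    return n * d


def cumulative_eqd2(
    boost_metric_gy: float,
    n: int,
    alpha_beta: float,
    prior: PriorCourse | None = None,
) -> float:
    """EQD2 of a boost metric plus the EQD2 of the prior EBRT course (same tissue)."""
    prior = prior if prior is not None else PriorCourse()
    return eqd2_of_metric(boost_metric_gy, n, alpha_beta) + prior.eqd2(alpha_beta)
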