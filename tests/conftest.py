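"""Shared fixtures.

Expensive artifacts (phantoms, optimized plans) are session-scoped and shared
across tests.  Most plan-level tests run on a coarse 2.5 mm grid with a
reduced iteration budget — the surrogate's behaviour (peaks, valleys, OAR
sparing) is already fully expressed there — while the acceptance tests use
the default 1.25 mm planning resolution.
"""

from __future__ import annotations

import numpy as np
import pytest

import rodplan as rp

COARSE = dict(spacing_mm=2.5)
COARSE_ITERS = 150


@pytest.fixture(scope="session")
def coarse_phantom() -> rp.StructureSet:
    return rp.generate_phantom(rp.PhantomSpec(seed=3, **COARSE))


@pytest.fixture(scope="session")
def coarse_rods(coarse_phantom) -> rp.RodSet:
    return rp.generate_straight_rods(coarse_phantom["CTV"], rp.StraightRodGridSpec())


@pytest.fixture(scope="session")
def coarse_valley(coarse_phantom, coarse_rods) -> rp.StructureMask:
    return rp.make_valley(coarse_phantom["CTV"], coarse_rods, 3.0)


def _coarse_plan(phantom, rods, valley, strategy: str) -> dict:
    config = rp.OptimizerConfig(strategy=strategy, iterations=COARSE_ITERS)
    result = rp.optimize(phantom, rods, valley, config)
    dose, scale = rp.normalize_to_d90(result.dose, phantom["CTV"])
    return {"result": result, "dose": dose, "scale": scale, "config": config}


@pytest.fixture(scope="session")
def sfrt1_plan(coarse_phantom, coarse_rods, coarse_valley) -> dict:
    return _coarse_plan(coarse_phantom, coarse_rods, coarse_valley, "SFRT_1")


@pytest.fixture(scope="session")
def sfrt2_plan(coarse_phantom, coarse_rods) -> dict:
    return _coarse_plan(coarse_phantom, coarse_rods, None, "SFRT_2")


@pytest.fixture(scope="session")
def sbrt_plan(coarse_phantom) -> dict:
    return _coarse_plan(coarse_phantom, None, None, "SBRT")


@pytest.fixture(scope="session")
def box_target() -> rp.StructureMask:
    """60 mm cube target on a 1.25 mm grid, surrounded by empty margin."""
    grid = rp.VoxelGrid(shape=(64, 64, 64), spacing_mm=1.25)
    data = np.zeros(grid.shape, dtype=bool)
    data[8:56, 8:56, 8:56] = True
    return rp.StructureMask("box", grid, data)
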