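"""Shared fixtures: a desk-scale solver configuration and one solved toy panel.

The toy panel (6 small charge patterns on a shared backbone) is solved once
per session on a 49^3 grid at 0.6 A and reused by the skin, matrix and
acceptance tests; uniform-dielectric analytic checks build their own grids.
"""

import numpy as np
import pytest

from ems3d.pbgrid import GridGeometry, SolverConfig, solve_lpb
from ems3d.synthetic import make_toy_panel

DESK_N = 49
DESK_SPACING = 0.6


@pytest.fixture(scope="session")
def desk_config() -> SolverConfig:
    return SolverConfig(
        grid_points_per_side=DESK_N,
        spacing=DESK_SPACING,
        ionic_strength=0.15,
        eps_protein=2.0,
        eps_solvent=78.0,
        temperature=310.0,
    )


@pytest.fixture(scope="session")
def toy_molecules():
    return make_toy_panel(6, seed=1)


@pytest.fixture(scope="session")
def toy_geometry(toy_molecules) -> GridGeometry:
    return GridGeometry.centered(
        toy_molecules[0].geometric_center, DESK_N, DESK_SPACING
    )


@pytest.fixture(scope="session")
def toy_grids(toy_molecules, toy_geometry, desk_config):
    return [solve_lpb(m, desk_config, toy_geometry) for m in toy_molecules]


@pytest.fixture(scope="session")
def toy_panel(toy_molecules, toy_grids):
    return list(zip(toy_molecules, toy_grids))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
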