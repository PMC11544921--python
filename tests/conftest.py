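"""Shared fixtures.  The expensive solver artefacts (the 27-cell
scenario sweep and the Hertz benchmark run) are session-scoped and
reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from fruitdrop import explicit_fem as fem
from fruitdrop import synthetic_fruit as sf
from fruitdrop.experiments_rsm import run_scenario_grid
from fruitdrop.tissue_mechanics import MaterialParams, get_material


@pytest.fixture(scope="session")
def fruit_geometry():
    return sf.build_fruit_geometry()


@pytest.fixture(scope="session")
def fruit_mesh_4mm(fruit_geometry):
    return sf.generate_mesh(fruit_geometry, 4.0)


@pytest.fixture(scope="session")
def scenario_grid_4mm():
    """Full 3x3x3 factorial sweep on a 4 mm mesh (shared across tests;
    the trend/ordering checks do not need a production-resolution mesh)."""
    return run_scenario_grid(element_size=4.0)


@pytest.fixture(scope="session")
def hertz_run():
    """Elastic sphere dropped on a near-rigid plane, for the Hertz
    closed-form benchmark.

    The sphere material uses a near-zero Poisson ratio so that the
    benchmark isolates contact and integration accuracy from the
    volumetric overstiffness of linear tetrahedra (E* = E exactly).
    """
    mesh = sf.make_fixture("elastic_sphere", radius=10, element_size=1.5)
    mat = MaterialParams(
        name="hertz-gel", young_modulus=2.0, density=1000.0, poisson_ratio=1e-3
    )
    scn = fem.DropScenario(
        height=0.05,
        collision_angle=0,
        surface_material=get_material("steel"),
        sim_duration=0.005,
    )
    res = fem.run_drop_simulation(
        mesh, {"flesh": mat}, scn, plasticity=False, use_skin=False
    )
    radius_m = 0.01
    e_star = mat.young_modulus * 1e6 / (1 - mat.poisson_ratio**2)
    m = res.total_mass
    v0 = res.initial_speed
    d_max = (0.5 * m * v0**2 * 15 / (8 * e_star * np.sqrt(radius_m))) ** 0.4
    f_hertz = 4.0 / 3.0 * e_star * np.sqrt(radius_m) * d_max**1.5
    return {"result": res, "f_hertz": f_hertz, "d_max": d_max, "mesh": mesh}


def smoothed_peak_force(result, window_s: float = 2e-4) -> float:
    """Peak of the contact force after a short moving average that
    removes discrete-contact ringing (window well below the ~2 ms
    contact duration)."""
    w = max(1, int(window_s / result.dt))
    f = np.convolve(result.contact_force_total, np.ones(w) / w, mode="same")
    return float(f.max())
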