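import pytest

from megpac_rsn.mesh import grid_mesh, icosphere_mesh
from megpac_rsn.pac import FrequencyGrid
from megpac_rsn.simulate import NetworkSpec, SimulationConfig


@pytest.fixture(scope="session")
def ico0():
    return icosphere_mesh(0, 70.0)


@pytest.fixture(scope="session")
def ico1():
    return icosphere_mesh(1, 70.0)


@pytest.fixture(scope="session")
def ico2():
    return icosphere_mesh(2, 70.0)


@pytest.fixture(scope="session")
def gridmesh():
    return grid_mesh(11, 11, 2.0)


@pytest.fixture(scope="session")
def coarse_grid():
    return FrequencyGrid.coarse()


@pytest.fixture(scope="session")
def tiny_sim_config():
    """Minimal valid simulation: 12-vertex mesh, one planted network."""
    return SimulationConfig(
        mesh_spec={"kind": "icosphere", "subdivisions": 0, "radius": 70.0},
        networks=(NetworkSpec("planted", (0, 1, 2), 6.0, 100.0),),
        effect_regions=(),
        duration_s=20.0,
        fs=500.0,
    )
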