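import numpy as np
import pytest

import placode.placode_model as pm
import placode.synthetic_data as sd
import placode.tissue_geometry as tg


@pytest.fixture(scope="session")
def random_voronoi_mesh():
    """64 uniform seeds in a 4^3 periodic box."""
    rng = np.random.default_rng(11)
    box = tg.PeriodicBox((4.0, 4.0, 4.0))
    seeds = rng.uniform(0, 4, (64, 3))
    return tg.initialize_from_voronoi(seeds, box)


@pytest.fixture(scope="session")
def layered_mesh():
    """Typed 4x4 four-layer tissue with a small placode patch."""
    mesh, _ = sd.make_flat_tissue(4, 4, sd.DEFAULT_LAYERS, jitter=0.25, seed=3)
    mesh = tg.assign_cell_types(mesh, sd.DEFAULT_LAYERS, 1.2, mesh.box.L[:2] / 2)
    V = tg.all_cell_volumes(mesh)
    mesh.V0 = V.copy()
    s0 = np.array([5.0, 5.4, 5.4, 5.4])
    mesh.S0 = s0[mesh.cell_types] * V ** (2.0 / 3.0)
    return mesh


@pytest.fixture()
def typed_params(layered_mesh):
    return pm.default_energy_params(
        layered_mesh, sigma_k=0.5,
        wetting={"pp": 1.3, "ps": 0.9, "pm_ratio": 2.0})
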