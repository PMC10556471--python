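import numpy as np
import pytest

import csiplan as cp


@pytest.fixture(scope="session")
def default_phantom():
    """The default single-field study phantom: canal 30 cm, gap 2.5 cm, 3 mm grid."""
    spec = cp.PhantomSpec(seed=1)
    density, sv = cp.generate_phantom(spec)
    return spec, density, sv


@pytest.fixture(scope="session")
def default_plan(default_phantom):
    _, density, sv = default_phantom
    return cp.generate_plan(sv, density)


@pytest.fixture(scope="session")
def multiple_phantom():
    """A long-canal phantom requiring two matched spine fields."""
    spec = cp.PhantomSpec(seed=7, canal_length_cm=55.0)
    density, sv = cp.generate_phantom(spec)
    return spec, density, sv


@pytest.fixture(scope="session")
def multiple_plan(multiple_phantom):
    _, density, sv = multiple_phantom
    return cp.generate_plan(sv, density)


@pytest.fixture(scope="session")
def water_slab():
    """Half-space water phantom (surface at y=0, posterior source side)."""
    from csiplan.structures import Grid, DensityVolume

    g = Grid((2.0, 1.0, 2.0), (-60.0, -200.0, -60.0), (61, 201, 61))
    rho = np.zeros(g.shape, dtype=np.float32)
    rho[:, g.axis_coords(1) <= 0, :] = 1.0
    return DensityVolume(g, rho)
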