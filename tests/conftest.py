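import numpy as np
import pytest

from radbiodose.microdosimetry import CylindricalAssembly, GEOMETRY_PRESETS
from radbiodose.nuclides import EmissionLine, Nuclide, get_nuclide


@pytest.fixture(scope="session")
def at211():
    return get_nuclide("At-211")


@pytest.fixture(scope="session")
def i131():
    return get_nuclide("I-131")


@pytest.fixture(scope="session")
def colony_geometry():
    return GEOMETRY_PRESETS["colony_well"]


@pytest.fixture(scope="session")
def dsb_geometry():
    return GEOMETRY_PRESETS["dsb_well"]


@pytest.fixture(scope="session")
def mono_alpha_5mev():
    """Degenerate single-line alpha emitter for closed-form checks."""
    return Nuclide(
        name="TestAlpha",
        half_life_s=3600.0,
        emissions=(EmissionLine("alpha", 1.0, 5000.0),),
        energy_per_decay_kev=5000.0,
    )


@pytest.fixture(scope="session")
def huge_cell_geometry():
    """Cell layer vastly thicker than any alpha range: full absorption regime."""
    return CylindricalAssembly(diameter_mm=200.0, dish_height_mm=1.0,
                               cell_height_mm=50.0, solution_height_mm=50.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
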