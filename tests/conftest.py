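import numpy as np
import pytest

from drsvessel.tissue_model import (
    BeamSpec,
    CylindricalVessel,
    MCConfig,
    OpticalProperties,
    PhantomModel,
    PropertyTable,
)


@pytest.fixture(scope="session")
def wide_slab():
    """Effectively laterally infinite slab for 1-D comparisons."""
    return PhantomModel(thickness_mm=2.0, lateral_mm=1e6)


@pytest.fixture(scope="session")
def pencil_beam():
    return BeamSpec(spot_mm=0.01, wavelengths_nm=(500.0,))


@pytest.fixture
def fast_mc():
    return MCConfig(photons=10_000, seed=12345)


@pytest.fixture(scope="session")
def vessel_model():
    """Phantom resembling the epoxy/intralipid slab with a blood channel."""
    wl = np.linspace(400.0, 600.0, 5)
    background = PropertyTable(wl, 0.01, 2.0 * (wl / 500.0) ** -1, 0.0, 1.5)
    blood = PropertyTable(wl, 20.0, 6.0, 0.9, 1.37)
    vessel = CylindricalVessel(300.0, 0.65, blood)
    return PhantomModel(
        thickness_mm=2.0,
        lateral_mm=15.0,
        background=background,
        vessel=vessel,
    )
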