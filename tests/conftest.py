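import numpy as np
import pytest

from inhaledpm import (FluidProperties, MaterialParameters,
                       build_default_geometry, default_scenario,
                       make_analytic_field)


@pytest.fixture(scope="session")
def mat() -> MaterialParameters:
    return MaterialParameters()


@pytest.fixture(scope="session")
def fluid() -> FluidProperties:
    return FluidProperties()


@pytest.fixture(scope="session")
def geometry():
    return build_default_geometry()


@pytest.fixture(scope="session")
def default_field(geometry):
    sc = default_scenario()
    return sc.build_field(geometry)


@pytest.fixture(scope="session")
def pipe_field(geometry):
    return make_analytic_field("pipe_poiseuille", geometry, 60.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
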