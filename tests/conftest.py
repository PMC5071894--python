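import numpy as np
import pytest

from aeroscatter import (EllipsoidSpec, Material, bat_equivalent_ellipsoid,
                         tissue_default)


@pytest.fixture(scope="session")
def bat_material() -> Material:
    return tissue_default("bat_effective")


@pytest.fixture(scope="session")
def bat_ellipsoid() -> EllipsoidSpec:
    return bat_equivalent_ellipsoid()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160)
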