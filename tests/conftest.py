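import numpy as np
import pytest

from icisim import GeneralParameters, SpecificParameters


@pytest.fixture(scope="session")
def sp():
    return SpecificParameters()


@pytest.fixture(scope="session")
def gp():
    return GeneralParameters()


@pytest.fixture(scope="session")
def gp_small():
    """Tiny grid (m=3) with inert tumor/DC side, for routing oracles."""
    return GeneralParameters(
        m=3,
        p_div=(0.04, 0.03, 0.02, 0.01),
        mu=(1e-15, 1e-15, 1e-15, 1e-15, 1e-15),
        sigma_N=1e-15,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
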