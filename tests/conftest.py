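import numpy as np
import pytest

from cordsim import (DoseProtocol, build_grid, default_parameters,
                     nondimensionalize, simulate)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def sig(params):
    return params.signalling


@pytest.fixture(scope="session")
def dimless(params):
    return nondimensionalize(params)


@pytest.fixture(scope="session")
def small_grid(dimless):
    """Coarse grid for unit tests where spatial accuracy is not the point."""
    return build_grid(dimless.x_inner, 21)


@pytest.fixture(scope="session")
def fig3_run(params):
    """The reference bolus (S=4, 1.75 h) on the default grid, bistable."""
    return simulate(params, DoseProtocol.single_pulse(4.0, 1.75),
                    t_end_h=12.0, module="bistable")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260917)
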