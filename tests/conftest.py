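import numpy as np
import pytest

import mdmri


@pytest.fixture(scope="session")
def default_protocol():
    return mdmri.make_default_protocol(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def midrange_component():
    """Single mid-range component used across recovery tests."""
    return mdmri.DRComponent(d_par=1.5, d_perp=0.5, theta=1.0, phi=2.0,
                             d0=1.0, gamma_par=500.0, gamma_perp=120.0,
                             r1=0.8, r2=12.0)
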