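import numpy as np
import pytest

import soilrisk


@pytest.fixture(scope="session")
def default_config():
    return soilrisk.load_default_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture()
def simple_scenario():
    """Round-number exposure scenario for hand-checkable arithmetic."""
    return soilrisk.ExposureScenario(
        BW=60, EF=350, ED=30, IngR=100, SA=5000, AF=0.07, ABS=0.1,
        InhR=15, PEF=1.36e9, AT_ca=365 * 70, AT_nc=365 * 30, CF=1e-6,
    )
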