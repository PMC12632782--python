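import numpy as np
import pytest

from rgcsubunits import calibration_filters, calibration_synapse


@pytest.fixture(scope="session")
def filters():
    return calibration_filters()


@pytest.fixture(scope="session")
def synapse_default():
    return calibration_synapse()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
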