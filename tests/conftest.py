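import numpy as np
import pytest

from dwirepro.schemes import AcquisitionScheme, IVIM_BVALUES, dti_scheme


@pytest.fixture(scope="session")
def ivim_scheme():
    """The seven-b trace-weighted protocol acquired at every centre."""
    return AcquisitionScheme(np.array(IVIM_BVALUES))


@pytest.fixture(scope="session")
def adc_scheme():
    return AcquisitionScheme(np.array([0.0, 500.0, 1000.0]))


@pytest.fixture(scope="session")
def tensor_scheme():
    return dti_scheme(n_directions=32, b=1000.0, n_b0=1, seed=0)
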