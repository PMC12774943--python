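import numpy as np
import pytest

import verdictmri as v
from verdictmri.datasets import volume_layout


@pytest.fixture(scope="session")
def kidney_scheme():
    return v.kidney_full_protocol()


@pytest.fixture(scope="session")
def dw_index(kidney_scheme):
    """Column indices of the DW volumes in the combo-major layout."""
    _, dw_idx = volume_layout(kidney_scheme)
    return dw_idx


@pytest.fixture(scope="session")
def small_phantom():
    """Small noiseless-parameter phantom shared by fitting tests."""
    spec = v.PhantomSpec(shape=(8, 8, 2), snr=50.0, seed=5)
    return v.make_phantom(spec)


@pytest.fixture(scope="session")
def small_dataset(small_phantom, kidney_scheme):
    return v.simulate_signals(small_phantom, kidney_scheme)


@pytest.fixture(scope="session")
def noiseless_dataset(kidney_scheme):
    spec = v.PhantomSpec(shape=(6, 6, 1), snr=None, seed=9)
    ph = v.make_phantom(spec)
    return ph, v.simulate_signals(ph, kidney_scheme)
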