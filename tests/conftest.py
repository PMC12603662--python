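import numpy as np
import pytest

from freewater.acquisition import DWIDataset
from freewater.simulate import paper_scheme, simulate_phantom


@pytest.fixture(scope="session")
def scheme():
    """The reference 3-shell acquisition (250 measurements)."""
    return paper_scheme(seed=0)


@pytest.fixture(scope="session")
def phantom_noiseless():
    ds, truth, labels = simulate_phantom(shape=(20, 20, 5), snr=np.inf, seed=3)
    return ds, truth, labels


@pytest.fixture(scope="session")
def phantom_snr40():
    ds, truth, labels = simulate_phantom(shape=(20, 20, 5), snr=40.0, seed=3)
    return ds, truth, labels


@pytest.fixture()
def single_voxel_ds(scheme):
    """One-voxel dataset factory bound to the reference scheme."""

    def make(signal):
        signal = np.asarray(signal, dtype=float)
        return DWIDataset(
            data=signal.reshape(1, 1, 1, -1),
            scheme=scheme,
            mask=np.ones((1, 1, 1), dtype=bool),
        )

    return make
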