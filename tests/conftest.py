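import numpy as np
import pytest

from spfcm.fcm import DataMatrix
from spfcm.simulate import SyntheticSpec, generate_gaussian_mixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_blobs():
    """Two well-separated spherical blobs with ground truth."""
    X, labels = generate_gaussian_mixture(
        SyntheticSpec(K=2, N=120, P=2, separation=10.0, seed=7)
    )
    return X, labels


@pytest.fixture
def four_blobs():
    X, labels = generate_gaussian_mixture(
        SyntheticSpec(K=4, N=400, P=2, separation=10.0, seed=11)
    )
    return X, labels


@pytest.fixture
def random_data(rng):
    return DataMatrix(rng.normal(size=(20, 3)))
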