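import numpy as np
import pytest

import sqishnet as sq


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default WBC-like synthetic dataset, fixed seed."""
    return sq.generate_synthetic(seed=42)


@pytest.fixture(scope="session")
def fitted_results(synthetic_dataset):
    """A quickly-trained classifier on the default synthetic data, shared
    across tests that need realistic fitted weights."""
    model = sq.SqishNetClassifier.from_dataset(synthetic_dataset)
    return model.fit(epochs=60, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
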