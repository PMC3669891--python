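import numpy as np
import pytest

from localqsar import FixtureSpec, generate_classification_fixture, generate_regression_fixture


@pytest.fixture(scope="session")
def clf_dataset():
    """Small planted-toxicophore classification dataset shared across tests."""
    return generate_classification_fixture(FixtureSpec(n_compounds=80, seed=7))


@pytest.fixture(scope="session")
def clf_dataset_clean():
    """Noise-free variant: label is exactly the carrier flag."""
    return generate_classification_fixture(FixtureSpec(n_compounds=60, label_noise=0.0, seed=5))


@pytest.fixture(scope="session")
def reg_dataset():
    return generate_regression_fixture(FixtureSpec(n_compounds=80, seed=11))


@pytest.fixture()
def random_fingerprints():
    """Deterministic batch of random binary fingerprints (20 x 12)."""
    rng = np.random.default_rng(123)
    return rng.integers(0, 2, size=(20, 12))
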