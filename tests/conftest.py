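import numpy as np
import pytest

from quadpre import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small strong-signal dataset shared across tests (12/class, 3 folds)."""
    return generate_dataset(SyntheticSpec(seed=7, n_per_class=12, n_folds=3))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_sequence(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet), size=length))
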