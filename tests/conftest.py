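import numpy as np
import pytest

from deeplip.synthetic_data import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """20 deterministic synthetic complexes (shared across tests)."""
    spec = SyntheticSpec(n_samples=20, seed=42)
    samples, manifest = generate_dataset(spec)
    return samples, manifest, spec


@pytest.fixture(scope="session")
def one_sample(small_dataset):
    return small_dataset[0][0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
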