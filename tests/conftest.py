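import numpy as np
import pytest

from circwave.phantom import PhantomSpec, generate_dataset


@pytest.fixture(scope="session")
def small_spec():
    """A small but structurally complete phantom dataset spec."""
    return PhantomSpec(n_subjects_per_class=3, scans_per_subject=5, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
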