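import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_case():
    """One deterministic left-laterality phantom with two masses."""
    from mammoseg.synthetic import generate_case

    return generate_case(seed=7, side=256, n_masses=2, laterality="left")
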