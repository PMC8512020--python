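import numpy as np
import pytest

import fundusedge as fe


@pytest.fixture(scope="session")
def default_phantom():
    """One default-condition phantom shared across read-only tests."""
    return fe.generate(fe.PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def clean_vessel_phantom():
    """Noiseless single high-contrast vessel with known boundary truth."""
    spec = fe.PhantomSpec(
        seed=5, n_vessels=1, widths=(5,), contrasts=(90.0,),
        noise_sigma=0.0, branch_prob=0.0,
    )
    return fe.generate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
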