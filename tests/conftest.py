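import numpy as np
import pytest

from pelvimetry import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_case():
    """One deterministic phantom shared across the suite."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def split_case():
    """Phantom whose urethra is split into two parts by a 2-row gap."""
    return generate_phantom(PhantomSpec(seed=1, split_gap_rows=2))


@pytest.fixture
def rng():
    return np.random.default_rng(20240102)
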