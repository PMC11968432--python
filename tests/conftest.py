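import numpy as np
import pytest

from nmdp.synthetic import SimSpec, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests."""
    return simulate_cohort(SimSpec(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for the slower end-to-end style tests."""
    spec = SimSpec(n_samples=60, m_expr=90, m_cnv=85, m_meth=100,
                   n_background_edges=30, seed=3)
    return simulate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
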