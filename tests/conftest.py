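import numpy as np
import pytest

from mitopair import fixtures
from mitopair.simulate import SimulationConfig, simulate_pair


@pytest.fixture(scope="session")
def table_f():
    return fixtures.feature_table_f()


@pytest.fixture(scope="session")
def table_m():
    return fixtures.feature_table_m()


@pytest.fixture(scope="session")
def codons_f():
    return fixtures.codon_counts("F")


@pytest.fixture(scope="session")
def codons_m():
    return fixtures.codon_counts("M")


@pytest.fixture(scope="session")
def sim_pair():
    """One default synthetic F/M pair shared by read-only tests."""
    return simulate_pair(SimulationConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(97)
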