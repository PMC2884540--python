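import numpy as np
import pytest

from phylobench import Alignment, SimulationConfig, comb_tree, simulate_orthologs


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_alignment(*rows, ids=None, alphabet=None):
    ids = ids or [f"t{i + 1}" for i in range(len(rows))]
    return Alignment(ids=list(ids), rows=list(rows), alphabet=alphabet)


@pytest.fixture
def six_taxon_reference():
    return comb_tree([f"s{i + 1}" for i in range(6)])


@pytest.fixture(scope="session")
def small_simulated_family():
    return simulate_orthologs(SimulationConfig(seed=424242))
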