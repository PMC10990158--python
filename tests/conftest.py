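import numpy as np
import pytest

from dib.boolean_circuit import BooleanCircuit, truth_table


@pytest.fixture(scope="session")
def and2_table():
    return truth_table(BooleanCircuit(2, (("AND", (0, 1)),), 2))


@pytest.fixture(scope="session")
def xor2_table():
    return truth_table(BooleanCircuit(2, (("XOR", (0, 1)),), 2))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
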