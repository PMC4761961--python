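from __future__ import annotations

import numpy as np
import pytest

from aptascreen.consensus_ranking import load_table2
from aptascreen.hairpin_energy import load_default_table, load_table3
from aptascreen.itc_binding import load_table4
from aptascreen.sequence_pool import load_table1


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table2():
    return load_table2()


@pytest.fixture(scope="session")
def table3():
    return load_table3()


@pytest.fixture(scope="session")
def table4():
    return load_table4()


@pytest.fixture(scope="session")
def nn_table():
    return load_default_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160222)


def random_rna_corpus(n, rng, min_len=8, max_len=20):
    """Random RNA sequences of length <= 20 for oracle-equivalence sweeps."""
    bases = np.array(list("ACGU"))
    return [
        "".join(rng.choice(bases, size=rng.integers(min_len, max_len + 1)))
        for _ in range(n)
    ]
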