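import numpy as np
import pandas as pd
import pytest

from bgcomp.datamodel import MissingTable


@pytest.fixture()
def toy_table():
    """The eight-row worked-example table (four complete cases)."""
    from bgcomp.synthetic import toy_example_table

    return toy_example_table()


@pytest.fixture(scope="session")
def dutch_table():
    from bgcomp.synthetic import gen_dutch_boys

    table, truth = gen_dutch_boys(n=537, seed=5)
    return table, truth


@pytest.fixture(scope="session")
def micro_table():
    from bgcomp.synthetic import gen_microcephaly

    table, truth = gen_microcephaly(n=900, seed=7)
    return table, truth


def make_table(columns, roles, binary=()):
    """Small helper to build a MissingTable from plain column dicts."""
    return MissingTable(data=pd.DataFrame(columns), roles=roles, binary=frozenset(binary))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
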