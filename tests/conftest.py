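import pytest

from maolie import datasets
from maolie.lie_engine import ki_to_dg


@pytest.fixture(scope="session")
def table1_summaries():
    return datasets.table1_summaries()


@pytest.fixture(scope="session")
def table2():
    return datasets.load_table2()


@pytest.fixture(scope="session")
def compounds():
    return datasets.table2_compounds()


@pytest.fixture(scope="session")
def dg_exp(compounds):
    return [ki_to_dg(c) for c in compounds]
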