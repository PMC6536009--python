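import numpy as np
import pytest

import regfine as rf


@pytest.fixture(scope="session")
def table1():
    return rf.load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return rf.load_fixture("table2")


@pytest.fixture(scope="session")
def table3():
    return rf.load_fixture("table3")


@pytest.fixture(scope="session")
def cohorts():
    return rf.fixture_cohorts()


@pytest.fixture(scope="session")
def annotations():
    return rf.fixture_annotations()


@pytest.fixture(scope="session")
def table2_records():
    return rf.fixture_table2_records()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
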