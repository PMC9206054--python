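import pytest

from lineup_sdt import BinningScheme, table2_fixture


@pytest.fixture(scope="session")
def young_control():
    return table2_fixture("young", "control")


@pytest.fixture(scope="session")
def young_experimental():
    return table2_fixture("young", "experimental")


@pytest.fixture(scope="session")
def older_control():
    return table2_fixture("older", "control")


@pytest.fixture(scope="session")
def older_experimental():
    return table2_fixture("older", "experimental")


@pytest.fixture(scope="session")
def scheme():
    return BinningScheme()
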