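import pytest

from snpmeta import by_snp, load_table1


@pytest.fixture(scope="session")
def table1():
    """The packaged 12-study fixture, reconciled."""
    return load_table1(validated=True)


@pytest.fixture(scope="session")
def table1_raw():
    """The packaged fixture as printed, before reconciliation."""
    return load_table1(validated=False)


@pytest.fixture(scope="session")
def rs1058205(table1):
    return by_snp(table1, "rs1058205")


@pytest.fixture(scope="session")
def rs2735839(table1):
    return by_snp(table1, "rs2735839")


@pytest.fixture(scope="session")
def rs266882(table1):
    return by_snp(table1, "rs266882")
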