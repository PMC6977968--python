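import pytest

from nascentclass.simulate import small_fixture


@pytest.fixture(scope="session")
def fixture_ds():
    """Miniature dataset (200 genes, 2 chromosomes) with every component."""
    return small_fixture()


@pytest.fixture(scope="session")
def counts_ds():
    return small_fixture(components=("counts",))


@pytest.fixture(scope="session")
def chec_ds():
    return small_fixture(components=("chec",), seed=3)


@pytest.fixture(scope="session")
def chip_ds():
    return small_fixture(components=("chip",), seed=2)
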