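import pytest

from sccosol import data


@pytest.fixture(scope="session")
def dataset():
    return data.load_clemastine_dataset()


@pytest.fixture(scope="session")
def clemastine():
    return data.load_clemastine()


@pytest.fixture(scope="session")
def co2():
    return data.load_co2()


@pytest.fixture(scope="session")
def table4():
    return data.load_density_constants()


@pytest.fixture(scope="session")
def table5():
    return data.load_eos_constants()


@pytest.fixture(scope="session")
def table6():
    return data.load_cluster_constants()
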