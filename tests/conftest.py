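import pytest

from strokecea import IPDGeneratorSpec, generate_ipd, paper_fixture


@pytest.fixture(scope="session")
def params():
    """The published base-case parameter set (read-only across tests)."""
    return paper_fixture()


@pytest.fixture()
def params_copy(params):
    return params.copy()


@pytest.fixture(scope="session")
def ipd():
    """A 1,200-patient synthetic trial table with a fixed seed."""
    return generate_ipd(IPDGeneratorSpec(n=1200, seed=3))
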