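import pytest

from padcea import default_fixture


@pytest.fixture(scope="session")
def fixture_pair():
    return default_fixture()


@pytest.fixture(scope="session")
def params(fixture_pair):
    return fixture_pair[0]


@pytest.fixture(scope="session")
def manifest(fixture_pair):
    return fixture_pair[1]
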