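import pytest

import pmcindex as px


@pytest.fixture(scope="session")
def schema():
    return px.default_schema()


@pytest.fixture(scope="session")
def fixture28():
    """Bundled 28-policy coding matrix + metadata."""
    return px.reference_fixture()


@pytest.fixture(scope="session")
def scored28(fixture28, schema):
    matrix, _ = fixture28
    return px.score_corpus(matrix, schema)
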