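import pytest

from xgrkit.fixtures import generate_fixtures


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One synthetic knowledgebase + input bundle shared across tests."""
    out = tmp_path_factory.mktemp("fixtures")
    return generate_fixtures(out, seed=1)
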