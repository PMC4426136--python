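import pytest

from tpmnom import build_gene_models, packaged_registry


@pytest.fixture(scope="session")
def records():
    return packaged_registry()


@pytest.fixture(scope="session")
def models(records):
    return build_gene_models(records)
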