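import pytest

from chapnet.evidence import rank_evidence
from chapnet.resources import packaged_catalog, packaged_evidence


@pytest.fixture(scope="session")
def catalog():
    return packaged_catalog()


@pytest.fixture(scope="session")
def evidence():
    return packaged_evidence()


@pytest.fixture(scope="session")
def rank_table(catalog, evidence):
    return rank_evidence(catalog, evidence)
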