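import pytest

from foodrisk import builtin_registry, compute_risk_table, load_brassica


@pytest.fixture(scope="session")
def brassica():
    return load_brassica()


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def risk_table(brassica):
    return compute_risk_table(brassica)
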