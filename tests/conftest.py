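import pytest
from hypothesis import settings

from repliclin import assess_pair, load_fixture_table3

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table3():
    return load_fixture_table3()


@pytest.fixture(scope="session")
def verdicts3(table3):
    return [assess_pair(p) for p in table3]
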