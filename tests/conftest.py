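import pytest

from tascea import degenerate_scenarios, paper_scenario


@pytest.fixture(scope="session")
def paper():
    return paper_scenario()


@pytest.fixture(scope="session")
def degenerate():
    return degenerate_scenarios()
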