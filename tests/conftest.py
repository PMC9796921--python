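import pytest

from quadchim.scheme import build_paper_scheme, build_three_group_scheme


@pytest.fixture(scope="session")
def paper_scheme():
    return build_paper_scheme()


@pytest.fixture(scope="session")
def demo_scheme():
    return build_three_group_scheme()
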