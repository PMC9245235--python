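import pytest

from pharmsched import builtin_cases, fixture_kb


@pytest.fixture(scope="session")
def kb():
    return fixture_kb()


@pytest.fixture(scope="session")
def cases():
    return builtin_cases()


@pytest.fixture(scope="session")
def cases_by_class(cases):
    return {pc.planted_error_class: pc for pc in cases}
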