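import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("deterministic")

from camscan.fixtures import fixture_library
from camscan.phospho import load_site_table


@pytest.fixture(scope="session")
def fixtures_by_name():
    return {fx.name: fx for fx in fixture_library()}


@pytest.fixture(scope="session")
def site_table():
    return load_site_table()
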