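import pytest

from aquarisk import load_fixture


@pytest.fixture(scope="session")
def fluoride_panel():
    return load_fixture("fluoride_table2")


@pytest.fixture(scope="session")
def nitrate_panel():
    return load_fixture("nitrate_table2")


@pytest.fixture(scope="session")
def profiles():
    return load_fixture("exposure_table1")


@pytest.fixture(scope="session")
def profile_map(profiles):
    return {p.group: p for p in profiles}
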