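import pytest

from vitd_cua import default_table, null_scenario


@pytest.fixture(scope="session")
def base_table():
    """The published base-case parameter table."""
    return default_table()


@pytest.fixture(scope="session")
def null_table():
    """Relative risk fixed at 1, zero supplement cost: increments are exactly 0."""
    return null_scenario()
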