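import pytest

from lcoscreen import enumerate_candidates, read_structure_inventory
from lcoscreen.candidates import DEFAULT_CONFIG


@pytest.fixture(scope="session")
def inventory():
    """The digitized 36-structure detection inventory shipped with the package."""
    return read_structure_inventory()


@pytest.fixture(scope="session")
def default_db():
    """The default enumerated candidate database (shared; treat as read-only)."""
    return enumerate_candidates(DEFAULT_CONFIG)
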