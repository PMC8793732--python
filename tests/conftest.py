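import pytest
from hypothesis import settings

from neckmetrics import load_all_fixtures
from neckmetrics.measurements_io import load_printed_summary

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixtures():
    """The six bundled reference columns, keyed by public fixture name."""
    return load_all_fixtures()


@pytest.fixture(scope="session")
def printed_summary():
    """Printed per-specimen summary cells, indexed by specimen_id."""
    return load_printed_summary().set_index("specimen_id")
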