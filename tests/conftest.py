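import pytest

from lasamatch import MatchParams, reference_pairs


@pytest.fixture(scope="session")
def reference():
    """The packaged 100-row reference pair table."""
    return reference_pairs()


@pytest.fixture()
def markers_off():
    """Calibrated convention minus the end-marker channels."""
    return MatchParams(end_markers=False)
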