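import pytest

from qcpost import RecordSet
from qcpost.datasets import cellulose_frontier_records


@pytest.fixture(scope="session")
def frontier_records() -> RecordSet:
    """The nine functionalized-cellulose frontier-orbital records."""
    return RecordSet(cellulose_frontier_records())
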