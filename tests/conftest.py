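import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ecohab.rfid_io import RawEvent
from ecohab.topology import standard_topology

# fixed epoch anchor on an exact hour boundary: 2015-02-16 12:00:00 UTC
T0_MS = 1_424_088_000_000


@pytest.fixture(scope="session")
def std_top():
    return standard_topology()


def make_event(t_ms, antenna, mouse="90001020000001", number=1, duration=100, tag=None):
    """Event at T0 + t_ms for test construction."""
    return RawEvent(
        event_number=number,
        timestamp_ms=T0_MS + int(t_ms),
        antenna_id=antenna,
        readout_duration_ms=duration,
        transponder_code=mouse,
        tag_name=tag,
    )
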