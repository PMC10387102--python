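import numpy as np
import pytest

from mfnet.geometry import build_default_layout
from mfnet.recording import FilteredRecording


@pytest.fixture(scope="session")
def layout():
    return build_default_layout()


@pytest.fixture
def small_layout_config():
    """2x2 grid, no exclusions, one compartment per column, one reference."""
    return {
        "grid": {"rows": 2, "cols": 2, "pitch_um": 100.0, "excluded": []},
        "compartments": {"somatic_chamber_A": [1, 1], "long_microchannel": [2, 2]},
        "references": {"R1": [1, 2]},
    }


def as_filtered(traces, sampling_rate=10_000.0, channel_ids=None):
    """Wrap plain arrays as a FilteredRecording for detection-level tests."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if channel_ids is None:
        channel_ids = [f"ch{i}" for i in range(traces.shape[0])]
    return FilteredRecording(
        traces=traces, sampling_rate=sampling_rate, channel_ids=channel_ids
    )
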