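import numpy as np
import pytest

from estrocycle.photometry import EpochInterval, ProcessedTrace


@pytest.fixture
def did_schedule():
    """Standard modified-DID access schedule: 1 h W1, 2 h EtOH, 30 min W2."""
    return [
        EpochInterval("W1", 0.0, 3600.0),
        EpochInterval("EtOH", 3600.0, 10800.0),
        EpochInterval("W2", 10800.0, 12600.0),
    ]


def make_trace(z, fs_eff=10.0, t0=0.0):
    """Wrap a z array in a ProcessedTrace on a uniform grid."""
    z = np.asarray(z, dtype=float)
    return ProcessedTrace(time_s=t0 + np.arange(len(z)) / fs_eff, z=z,
                          fs_eff=fs_eff)


@pytest.fixture
def trace_factory():
    return make_trace
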