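import numpy as np
import pytest

import rfneurostim as rf


@pytest.fixture
def short_protocol() -> rf.StimulusProtocol:
    """60 trials of 3 s ON / 3 s OFF at the imaging-experiment power."""
    return rf.make_protocol(60, 3.0, 3.0, 37.5)


@pytest.fixture
def study_protocol() -> rf.StimulusProtocol:
    """300 trials of 3 s ON / 3 s OFF (30-minute session)."""
    return rf.make_protocol(300, 3.0, 3.0, 37.5)


def spike_set(spike_lists) -> rf.SpikeTrainSet:
    """Hand-built SpikeTrainSet for constructed-example tests."""
    import pandas as pd

    arrays = [np.asarray(s, dtype=float) for s in spike_lists]
    ids = np.arange(len(arrays))
    gt = pd.DataFrame(index=pd.Index(ids, name="unit_id"))
    return rf.SpikeTrainSet(spike_times=arrays, unit_ids=ids, ground_truth=gt)


@pytest.fixture
def make_spikes():
    return spike_set
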