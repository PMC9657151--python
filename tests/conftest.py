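import logging

import numpy as np
import pytest

from rtqwt import EpochedDataset, SynthSpec, bandpass, generate

# the feature table logs one line per imputed deep subband; keep test
# output readable without hiding real warnings from other modules
logging.getLogger("rtqwt.features").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synth_dataset():
    """Small two-class dataset with channel 1 informative (band-passed)."""
    ds = generate(
        SynthSpec(
            n_channels=3,
            n_epochs_per_class=15,
            class_power_ratio=2.5,
            snr_db=0.0,
            informative_channel=1,
            seed=7,
        )
    )
    return EpochedDataset(
        epochs=bandpass(ds.epochs, ds.fs), labels=ds.labels, fs=ds.fs,
        channel_names=list(ds.channel_names),
    )
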