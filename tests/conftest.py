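import numpy as np
import pytest

import semgmap as sm


@pytest.fixture(scope="session")
def grid():
    return sm.ElectrodeGrid()


@pytest.fixture(scope="session")
def short_recording():
    """Cheap synthetic recording: 1 s ramps, 2 s hold, plateau 2,048 samples."""
    return sm.simulate_recording(
        n_units=25,
        up_s=1.0,
        hold_s=2.0,
        down_s=1.0,
        plateau_samples=2048,
        noise_rms=0.05,
        seed=101,
    )


@pytest.fixture(scope="session")
def clean_plateau(short_recording):
    """Preprocessed plateau segment of the short recording."""
    rec = sm.mean_center(short_recording)
    rec = sm.segment_plateau(rec)
    return sm.bandpass_zero_lag(rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
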