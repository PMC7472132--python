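import numpy as np
import pytest

from ecgdenoise import ECGModelParams, bandpass, generate_ecg


@pytest.fixture(scope="session")
def clean_record():
    """10-s, 60-bpm synthetic ECG at 256 Hz with ground-truth peaks."""
    return generate_ecg(ECGModelParams(), 10.0, seed=7)


@pytest.fixture(scope="session")
def clean_filtered(clean_record):
    """The same record after the 3-25 Hz conditioning band-pass."""
    return bandpass(clean_record.samples, clean_record.fs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
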