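import numpy as np
import pytest

from phieeg.eeg_io import EEGRecording


@pytest.fixture()
def rng():
    return np.random.default_rng(20240930)


@pytest.fixture()
def small_recording():
    """Two-channel recording, 500 Hz, 1 s, deterministic content."""
    gen = np.random.default_rng(42)
    data = gen.normal(0.0, 50.0, size=(2, 500))
    return EEGRecording(
        subject_id="sub-000",
        sampling_rate=500.0,
        channels=["Fp1", "Fp2"],
        data=data,
        group="HC",
        age=70.0,
        sex="female",
    )


@pytest.fixture()
def montage_recording():
    """Full 19-channel recording, 500 Hz, 2 s."""
    from phieeg.eeg_io import MONTAGE_1020

    gen = np.random.default_rng(7)
    data = gen.normal(0.0, 50.0, size=(19, 1000))
    return EEGRecording(
        subject_id="sub-019",
        sampling_rate=500.0,
        channels=list(MONTAGE_1020),
        data=data,
    )
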