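import numpy as np
import pytest

from fscv import (
    RampWaveform,
    RecordingConfig,
    fit_pcr,
    generate_recording,
    make_templates,
    make_training_set,
)

NOMINAL_SENSITIVITY = 10.0  # nA/uM


@pytest.fixture(scope="session")
def waveform():
    return RampWaveform()


@pytest.fixture(scope="session")
def templates(waveform):
    return make_templates(waveform)


@pytest.fixture(scope="session")
def training_set():
    """Noiseless standard 5 DA + 3 acidic + 2 basic reference set."""
    return make_training_set(sensitivity_nA_per_uM=NOMINAL_SENSITIVITY)


@pytest.fixture(scope="session")
def pcr_model(training_set):
    return fit_pcr(training_set)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, drift-free, homogeneous-sensitivity study conditions."""
    return RecordingConfig(
        noise_sd_nA=0.0,
        sensitivity_cv=0.0,
        drift_exp_frac=0.0,
        drift_rw_frac_per_scan=0.0,
        ph_drift_amplitude=0.0,
        n_channels=4,
    )


@pytest.fixture(scope="session")
def clean_recording(clean_config):
    return generate_recording(clean_config, seed=11)


@pytest.fixture(scope="session")
def default_recording():
    """Default (noisy, drifting, heterogeneous) 16-channel recording."""
    return generate_recording(RecordingConfig(), seed=7)
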