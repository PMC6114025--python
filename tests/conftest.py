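import numpy as np
import pytest

from oculobox import (RawRecording, SimSubjectParams, StimulusProtocol,
                      simulate_recording)


@pytest.fixture(scope="session")
def protocol():
    """Full default protocol: 500 Hz, 220 s, five 40 s cycles."""
    return StimulusProtocol()


@pytest.fixture(scope="session")
def fast_protocol():
    """Same layout at 100 Hz for cheap tests."""
    return StimulusProtocol(sampling_rate=100)


@pytest.fixture(scope="session")
def noiseless_recording(protocol):
    return simulate_recording(SimSubjectParams(seed=0), protocol)


@pytest.fixture(scope="session")
def noisy_recording(protocol):
    params = SimSubjectParams(seed=7, tracking_noise_sd=0.5,
                              disconjugacy_sd=1.0, blink_rate=12.0)
    return simulate_recording(params, protocol)


def make_recording(protocol, left_x, left_y, right_x, right_y,
                   valid=None, subject_id="manual"):
    """Assemble a RawRecording from coordinate arrays."""
    n = protocol.n_samples
    t = np.arange(n) / protocol.sampling_rate
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return RawRecording(subject_id, t, np.asarray(left_x, float),
                        np.asarray(left_y, float), np.asarray(right_x, float),
                        np.asarray(right_y, float), valid.copy(), valid.copy())
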