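"""Shared synthetic fixtures (generated at test time; nothing on disk)."""

import pytest

from gazelab import synthetic
from gazelab.model import TargetSet


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free, dropout-free, sway-free, zero inter-eye offset: the exact
    limit in which the pipeline must recover targets perfectly."""
    return synthetic.SimulationParams(
        angular_noise_sd=0.0, dropout_rate=0.0, sway_amplitude=0.0,
        inter_eye_offset=0.0, seed=1)


@pytest.fixture(scope="session")
def clean_recording(clean_params):
    return synthetic.synthesize_recording(clean_params)


@pytest.fixture(scope="session")
def noisy_recording():
    """Default study-emulating conditions (jitter, sway, dropout)."""
    return synthetic.synthesize_recording(synthetic.SimulationParams(seed=7))


@pytest.fixture(scope="session")
def targets():
    return TargetSet.canonical()
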