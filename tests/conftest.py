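"""Shared fixtures: tiny model configs and synthetic sessions."""

import numpy as np
import pytest

from cveegnet import ModelConfig, SynthSpec, generate_session
from cveegnet.spectral import segment_session


@pytest.fixture
def tiny_config():
    """A miniature architecture for fast structural/gradient tests."""
    return ModelConfig(C=4, T=16, F1=2, D=2, F2=4, k_spec=5, k_sep=5,
                       pool1=2, pool2=2, hidden=8, n_classes=3)


@pytest.fixture(scope="session")
def amplitude_session():
    """Small amplitude-coded session: class k boosts band k."""
    spec = SynthSpec(K=3, C=8, fs=200.0, trial_seconds=2.0, trials_per_class=10,
                     coding="amplitude", snr=5.0, seed=21)
    return generate_session(spec)


@pytest.fixture(scope="session")
def phase_session():
    """Small phase-coded session: matched amplitudes, class in group phase."""
    spec = SynthSpec(K=2, C=8, fs=200.0, trial_seconds=2.0, trials_per_class=25,
                     coding="phase", bands=((10.0, 10.0, 1.0),), snr=5.0, seed=22)
    return generate_session(spec)


@pytest.fixture(scope="session")
def amplitude_segments(amplitude_session):
    return segment_session(amplitude_session)
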