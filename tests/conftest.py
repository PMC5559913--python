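"""Shared fixtures: synthetic trials are generated once per session."""

import pytest

from footload.io_formats import SubjectProfile
from footload.pipeline import estimate_trial
from footload.synthetic import GaitSimConfig, simulate_trial


@pytest.fixture(scope="session")
def subject():
    return SubjectProfile("sim", 61.0)


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free corridor trial: 32 complete steps (30 after exclusions)."""
    return simulate_trial(GaitSimConfig(n_steps=32, seed=1))


@pytest.fixture(scope="session")
def clean_estimate(clean_trial, subject):
    return estimate_trial(clean_trial.recordings, subject, mode="full")


@pytest.fixture(scope="session")
def noisy_trial():
    """Corridor trial with sensor noise at the levels the detector must survive."""
    return simulate_trial(
        GaitSimConfig(
            n_steps=36, seed=2,
            accel_noise_sd=0.5, gyro_noise_sd=0.05, force_noise_sd=0.5,
        )
    )


@pytest.fixture(scope="session")
def foot_dominated_trial():
    return simulate_trial(GaitSimConfig(n_steps=20, seed=4, foot_dominated=True))
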