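import numpy as np
import pytest

from fogcast import (
    GaitSimConfig,
    ParticipantProfile,
    WindowSpec,
    build_signal_bundle,
    make_windows,
    simulate_trial,
)


@pytest.fixture(scope="session")
def short_config():
    return GaitSimConfig(trial_duration=30.0, seed=42)


@pytest.fixture(scope="session")
def freezer_profile():
    return ParticipantProfile("P01", "left", True)


@pytest.fixture(scope="session")
def freezer_trial(short_config, freezer_profile):
    return simulate_trial(short_config, freezer_profile, "P01_T00")


@pytest.fixture(scope="session")
def freezer_bundle(freezer_trial):
    return build_signal_bundle(freezer_trial)


@pytest.fixture(scope="session")
def freezer_windows(freezer_trial):
    return make_windows(freezer_trial, WindowSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
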