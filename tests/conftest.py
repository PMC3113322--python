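import dataclasses

import numpy as np
import pytest

from gaitsock.synthcohort import make_profile, simulate_trial

# overrides that strip every stochastic trial-level component: identical,
# noise-free trials whose sensor features sit exactly at the template phases
DEGENERATE = dict(
    noise_sd_v=0.0,
    timing_jitter_sd_s=0.0,
    drift_rate_v_per_s=0.0,
    drift_sine_amp_v=0.0,
    kinematic_mismatch=0.0,
)


@pytest.fixture(scope="session")
def degenerate_profile():
    return dataclasses.replace(make_profile("sock_only", 1), **DEGENERATE)


@pytest.fixture(scope="session")
def degenerate_trial(degenerate_profile):
    return simulate_trial(degenerate_profile, 7)


@pytest.fixture(scope="session")
def degenerate_trials(degenerate_profile):
    """Ten identical noise-free trials of one subject."""
    return [simulate_trial(degenerate_profile, s, trial_index=s) for s in range(10)]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
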