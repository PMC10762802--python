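import numpy as np
import pytest

from gazeshift import (BehaviorParams, PlantParams, build_standard_protocol,
                       simulate_session)


@pytest.fixture(scope="session")
def standard_protocol():
    return build_standard_protocol(seed=0)


@pytest.fixture
def noiseless_params():
    """Deterministic plant: no measurement noise, no trial-to-trial jitter."""
    return PlantParams(noise_sd_dps=0.0, eye_noise_sd_deg=0.0, trial_jitter_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_session(standard_protocol):
    """One noiseless simulated session plus its ground truth."""
    params = PlantParams(noise_sd_dps=0.0, eye_noise_sd_deg=0.0, trial_jitter_sd=0.0)
    rec, truths = simulate_session(
        params, standard_protocol, BehaviorParams(), np.random.default_rng(7)
    )
    return rec, truths
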