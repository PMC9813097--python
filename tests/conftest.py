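import numpy as np
import pytest

from okrent.synthetic_data import (
    AnimalSpec,
    PlasticityParams,
    StimulusProfile,
    simulate_animal,
)


@pytest.fixture(scope="session")
def short_profile() -> StimulusProfile:
    """Stimulus 4 (4 deg/s, 10 s cycles) shortened to 200 s (20 cycles)."""
    return StimulusProfile(speed=4.0, period=10.0, duration=200.0)


@pytest.fixture(scope="session")
def old_params_short(short_profile) -> PlasticityParams:
    """Old-group plasticity rule on the shortened session."""
    return PlasticityParams(
        slope_m=-0.59, setpoint_x0=6.4, cycle_count=short_profile.n_cycles
    )


@pytest.fixture(scope="session")
def clean_recording(short_profile, old_params_short):
    """One noiseless animal: regular 30 fps sampling, no fast phases."""
    spec = AnimalSpec(
        initial_amplitude=3.8,
        gain_noise_sd=0.0,
        fast_phase_rate=0.0,
        timestamp_jitter_sd=0.0,
        eye_noise_sd=0.0,
        seed=7,
    )
    rec, truth = simulate_animal(
        spec, short_profile, old_params_short, return_truth=True
    )
    return rec, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
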