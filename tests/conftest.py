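import numpy as np
import pytest

from clsleep import (
    StimulationConfig,
    generate_sleep_eeg,
    run_closed_loop,
)


@pytest.fixture(scope="session")
def night_sim():
    """One-hour N3 night with quasi-regularly recurring SOs plus the
    closed-loop run on it; shared by the invariant tests."""
    rec, truth = generate_sleep_eeg(
        3600.0, fs=500.0, channels=("Fpz",), so_rate=3.4, spindle_rate=0.0,
        placement="regular", seed=1)
    log = run_closed_loop(rec, StimulationConfig(), seed=0)
    return rec, truth, log


@pytest.fixture(scope="session")
def clean_rec():
    """20-min low-noise recording with isolated planted SOs and spindles."""
    rec, truth = generate_sleep_eeg(
        1200.0, fs=500.0, so_rate=3.4, spindle_rate=2.0, noise_sd=2.0,
        placement="regular", seed=3)
    return rec, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
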