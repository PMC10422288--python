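import numpy as np
import pytest

from faaswb import SessionConfig, generate_session, simulate_cohort


@pytest.fixture(scope="session")
def clean_session():
    """One default synthetic run (14 channels, 300 s, P = 30 s, seed 1)."""
    return generate_session(SessionConfig(seed=1), seed=1)


@pytest.fixture(scope="session")
def noiseless_session():
    """A run with no broadband noise and no log-power jitter: FAA ground
    truth is exactly a + b·SWB per block."""
    cfg = SessionConfig(noise_sd=0.0, broadband_noise_amp=0.0,
                        coupling_intercept=0.2, coupling_slope=0.1, seed=3)
    rec, trace = generate_session(cfg, seed=3)
    return cfg, rec, trace


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """A small on-disk cohort: 5 participants × 2 runs, one left-handed."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = SessionConfig(n_runs=2)
    manifest_path = simulate_cohort(out, 5, cfg, seed=42, n_left_handed=1)
    return manifest_path


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
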