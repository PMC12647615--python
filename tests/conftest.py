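import numpy as np
import pytest
import warnings

from hypothesis import settings

import effortnirs as en

warnings.filterwarnings("ignore", message=".*converge.*")

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def montage():
    return en.default_montage()


@pytest.fixture(scope="session")
def design():
    return en.make_session_design(n_blocks=4, seed=7)


@pytest.fixture(scope="session")
def noisy_session():
    """One simulated participant with default physiological noise."""
    rec, true_hb, truth = en.simulate_session("P00", seed=3)
    return rec, true_hb, truth


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free session: pure neural signal through the forward optics."""
    rec, true_hb, truth = en.simulate_session("P01", seed=3, noise=en.NoiseParams.off())
    return rec, true_hb, truth


@pytest.fixture(scope="session")
def pipeline_output(noisy_session):
    rec, _, _ = noisy_session
    hb, qc = en.run_pipeline(rec, en.PipelineParams())
    return rec, hb, qc


@pytest.fixture(scope="session")
def trial_table():
    """Direct synthetic long table at study-like size with known effects."""
    return en.simulate_trial_table(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
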