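import numpy as np
import pytest

from pupilexplore import synth


@pytest.fixture(scope="session")
def default_session():
    """One mid-sized synthetic session with ground truth (shared, read-only)."""
    return synth.generate_session(
        bandit=synth.BanditConfig(n_trials=800),
        seed=20240117,
        session_id=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
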