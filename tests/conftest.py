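import numpy as np
import pytest

from mivote import EpochSet, SynthConfig, generate_session


@pytest.fixture
def tiny_epochs():
    """2 trials x 3 channels x 100 samples with simple content."""
    rng = np.random.default_rng(0)
    return EpochSet(
        data=rng.normal(size=(2, 3, 100)).astype(np.float32),
        fs=250.0,
        channel_names=["C3", "Cz", "C4"],
        labels=["LH", "RH"],
    )


@pytest.fixture(scope="session")
def strong_erd_session():
    """Small session with a deep ERD effect, shared across tests."""
    return generate_session(SynthConfig(n_trials_per_class=12, erd_depth=0.8, seed=3))
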