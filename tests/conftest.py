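import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 4-participant, 2-background cohort small enough for fast tests."""
    from eeglisten.synth import CohortSpec

    return CohortSpec(
        n_participants=4, n_channels=12, fs=128.0, seed=7,
        backgrounds=("PK", "MT"), n_topics=4, n_background_fragments=2,
        fragment_duration_s={"LA": 30.0, "BA": 20.0, "BUA": 20.0})
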