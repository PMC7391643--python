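import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_study():
    """A small fixed synthetic study shared by mining/annotation tests."""
    from cyclomine import SimConfig, generate_precursor_set

    cfg = SimConfig(seed=11, n_cyclotide=10, n_decoy=20, truncation_prob=0.0)
    transcripts, truths = generate_precursor_set(cfg)
    return cfg, transcripts, truths


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
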