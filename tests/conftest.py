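import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_cfg():
    """A fast small-scale generator configuration shared across tests."""
    from szmirnet.synth import SynthConfig

    return SynthConfig(seed=11, n_mirna=40, n_genes=300,
                       tier_sizes=(300, 60, 10), n_probes=200)
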