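import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sfdkit import ProteinSet, SyntheticConfig, generate_proteomes

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_world():
    """A tiny noiseless synthetic world for exact-recovery tests."""
    config = SyntheticConfig(
        seed=7, n_scaffold=60, n_sources=4, n_source_specific=8,
        n_disease_unique=25, frac_function_annotated=0.4, n_patients=60,
        n_null_genes=5,
    )
    return generate_proteomes(config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_set(label, symbols):
    return ProteinSet.from_symbols(label, symbols)
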