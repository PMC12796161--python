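import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_bundle():
    """A small planted-mode cohort shared across tests."""
    from modecca.experiments import planted_spec
    from modecca.synthetic_cohort import generate_cohort

    spec = planted_spec(
        n_subjects=240,
        rho=0.5,
        seed=42,
        domain_sizes={"psqi": 4, "asr": 3, "gmv": 3, "motor": 3},
        family_size_range=(1, 2),
    )
    return generate_cohort(spec)
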