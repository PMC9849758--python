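import pytest
from hypothesis import settings

from slowbind import DEFAULT_ASSAYS, benchmark_panel
from slowbind.simulate import random_oracle_draws
from slowbind.studies import (
    irreversible_recovery_study,
    preincubation_ic50_study,
    reversible_recovery_study,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

#: fixed seed for the shared replicate studies; any value exercises the
#: same statistical claims
STUDY_SEED = 20219


@pytest.fixture(scope="session")
def tryptase_assay():
    return DEFAULT_ASSAYS["beta_tryptase"]


@pytest.fixture(scope="session")
def reversible_study():
    """20-replicate slow-tight-binding round trip (34b / beta-tryptase)."""
    return reversible_recovery_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def irreversible_study():
    """20-replicate irreversible round trip (46b / beta-tryptase)."""
    return irreversible_recovery_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def ic50_study():
    """20-replicate preincubation IC50 round trip (57b / beta-tryptase)."""
    return preincubation_ic50_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def oracle_draws():
    """50 random mechanisms in the pseudo-first-order validity regime."""
    return random_oracle_draws(seed=123, n=50)


@pytest.fixture(scope="session")
def classification_panel():
    """Standard 60-curve mechanism-classification benchmark."""
    return benchmark_panel(seed=42)
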