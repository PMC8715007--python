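import numpy as np
import pytest

from omicbridge import StudyConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared across read-only tests."""
    return generate_study(StudyConfig(seed=7))


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for fast pipeline-level tests."""
    cfg = StudyConfig(
        n_taxa=40, n_metabolites=60, n_indicators=5,
        n_responsive_taxa=3, n_mediating_metabolites=3, seed=11,
    )
    return generate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
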