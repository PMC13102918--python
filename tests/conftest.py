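import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from twinmiss import SimulationSpec, simulate_binary_liability, simulate_continuous


@pytest.fixture
def study_continuous():
    """An AE continuous dataset at the study's sample sizes."""
    spec = SimulationSpec(
        a2=0.53, c2=0.0, e2=0.47, n_mz_pairs=165, n_dz_pairs=132, seed=42
    )
    return simulate_continuous(spec)


@pytest.fixture
def study_binary():
    """A CE binary dataset at the study's sample sizes and prevalence."""
    spec = SimulationSpec(
        a2=0.0, c2=0.37, e2=0.63, n_mz_pairs=165, n_dz_pairs=132,
        trait_kind="binary", prevalence=0.396, seed=42,
    )
    return simulate_binary_liability(spec)


@pytest.fixture
def tiny_continuous():
    """A 30-pair continuous ACE dataset for brute-force oracle checks."""
    spec = SimulationSpec(
        a2=0.4, c2=0.3, e2=0.3, n_mz_pairs=16, n_dz_pairs=14, seed=11
    )
    return simulate_continuous(spec)


@pytest.fixture
def tiny_binary():
    """A 30-pair binary dataset for brute-force oracle checks."""
    spec = SimulationSpec(
        a2=0.3, c2=0.3, e2=0.4, n_mz_pairs=16, n_dz_pairs=14,
        trait_kind="binary", prevalence=0.4, seed=12,
    )
    return simulate_binary_liability(spec)
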