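import numpy as np
import pytest

from tgdrep.fixtures import (
    cohort_feature_counts,
    pilot_clone_fractions,
    pilot_major_sets,
    pilot_primary_mutations,
    pilot_repertoires,
)
from tgdrep.model import Chain
from tgdrep.synthdata import simulate_cohort, study_mimic_profiles


@pytest.fixture(scope="session")
def gamma_majors():
    return pilot_major_sets(Chain.TRG)


@pytest.fixture(scope="session")
def delta_majors():
    return pilot_major_sets(Chain.TRD)


@pytest.fixture(scope="session")
def pilot_reps():
    return pilot_repertoires()


@pytest.fixture(scope="session")
def feature_counts():
    return cohort_feature_counts()


@pytest.fixture(scope="session")
def clone_fractions():
    return pilot_clone_fractions()


@pytest.fixture(scope="session")
def primary_mutations():
    return pilot_primary_mutations()


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced study-like synthetic cohort shared across tests."""
    profiles = study_mimic_profiles(
        n_indolent=3, n_symptomatic=2, n_hstcl=1, n_controls=6,
        read_depth=50_000, background_clonotypes=150)
    return simulate_cohort(profiles, seed=2024)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
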