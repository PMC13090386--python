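import pytest

from rewirekit.core_model import Cohort
from rewirekit.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture
def small_cohort() -> Cohort:
    return Cohort(
        patients=["P1", "P2", "P3", "P4"],
        group={"P1": "case", "P2": "case", "P3": "control", "P4": "control"},
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One full-size synthetic cohort shared across read-only tests."""
    return simulate_cohort(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced cohort for fast structural checks."""
    return simulate_cohort(
        SimConfig(
            seed=3,
            n_genes=60,
            n_enhancers=150,
            n_variants=80,
            n_planted_goi=10,
            n_planted_loi=5,
            n_planted_discordant=5,
            n_imbalanced_genes=2,
            n_ase_null_genes=20,
            cells_per_type=20,
            n_de_per_type=5,
        )
    )
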