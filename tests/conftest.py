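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


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small planted-effect cohort (patients only, Fz) shared across tests."""
    from emoeeg import CohortSpec, generate_cohort

    spec = CohortSpec(n_normal=2, n_moderate=5, n_marked=5, seed=11,
                      electrodes=("Fz", "A1", "A2"))
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_feature_table(tiny_cohort):
    from emoeeg.cli_io import cohort_feature_table

    _, cohort = tiny_cohort
    return cohort_feature_table(cohort, methods=("ApEn",))
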