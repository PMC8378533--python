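import numpy as np
import pytest

from cogsurv import MCMCSettings, ModelSpec, fit_mlm, simulate_cohort
from cogsurv.synthetic import recovery_config


@pytest.fixture(scope="session")
def recovery_sim():
    """Moderate single-stratum cohort at known truth, shared across tests."""
    return simulate_cohort(recovery_config(seed=42, n=400))


@pytest.fixture(scope="session")
def recovery_fit(recovery_sim):
    cohort, panel, _ = recovery_sim
    return fit_mlm(
        panel,
        cohort,
        ModelSpec(form="quadratic"),
        MCMCSettings(chains=2, iterations=800, burn_in=300, seed=9),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
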