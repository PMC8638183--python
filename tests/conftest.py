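import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_run():
    """One scaled-down run of the full simulation factor grid.

    10 replicates per configuration (the reference design uses 100); shared
    across the evaluation-level tests so the sweep is executed once.
    """
    from fourquad.simulation import build_factor_grid, run_simulation

    grid = build_factor_grid(n_replicates=10, master_seed=1)
    return run_simulation(grid)


@pytest.fixture(scope="session")
def sim_tables(sim_run):
    from fourquad.evaluation import factor_tables

    return factor_tables(sim_run)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
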