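import numpy as np
import pytest

import famstate as fs


@pytest.fixture(scope="session")
def truth():
    return fs.default_truth()


@pytest.fixture(scope="session")
def small_sim(truth):
    """Modest simulated dataset reused across tests (deterministic)."""
    cfg = fs.recovery_config(n_individuals=300, n_occasions=15, seed=11)
    return fs.simulate_population(truth, cfg)


@pytest.fixture(scope="session")
def small_draws(small_sim):
    """A short but real MCMC run on the small dataset."""
    mcmc = fs.McmcConfig(n_chains=2, n_iterations=2500, n_burnin=1000, thin=5, seed=5)
    return fs.sample_posterior(small_sim.histories, mcmc)


def random_tables(rng: np.random.Generator) -> fs.ProbabilityTables:
    """A random valid set of probability tables (helper for oracle tests)."""
    layout = fs.ParamLayout()
    theta = rng.normal(0.0, 1.0, layout.n_params)
    theta[layout.p_indices] = rng.uniform(0.05, 0.95, 4)
    return layout.tables(theta)
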