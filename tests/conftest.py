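import numpy as np
import pandas as pd
import pytest

from txage import SimulationConfig, simulate_cohorts, simulate_methylation


@pytest.fixture(scope="session")
def tiny_config():
    """A desk-scale study: 3 cohorts, 80 genes, small samples."""
    return SimulationConfig(
        n_cohorts=3, n_per_cohort=120, n_genes=80, n_cpg_per_gene=3, seed=11
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    cohorts, genes = simulate_cohorts(tiny_config)
    cpgs = simulate_methylation(tiny_config, cohorts, genes)
    return tiny_config, cohorts, genes, cpgs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_matrix(rng):
    """A positive random samples-by-genes matrix with labels."""
    vals = rng.lognormal(mean=2.0, sigma=0.5, size=(8, 12))
    return pd.DataFrame(
        vals,
        index=[f"s{i}" for i in range(8)],
        columns=[f"g{j}" for j in range(12)],
    )
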