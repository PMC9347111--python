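import numpy as np
import pytest

from trimark.synthetic_data import (PopulationSpec, simulate_genotypes,
                                    table1_fixture)


@pytest.fixture(scope="session")
def table1():
    """The packaged 93 x 15 phenotype panel."""
    return table1_fixture()


@pytest.fixture(scope="session")
def recovery_sims():
    """Ten replicate two-population cohorts (F = 0.3, n = 100, m = 2000)
    used for the parameter-recovery checks."""
    sims = []
    for seed in range(10):
        g, q, labels = simulate_genotypes(
            PopulationSpec(n_samples=100, n_sites=2000, K=2, F=0.3, seed=seed))
        sims.append((g, q, labels))
    return sims


@pytest.fixture(scope="session")
def small_cohort():
    """One modest structured cohort for quick end-to-end checks."""
    return simulate_genotypes(
        PopulationSpec(n_samples=60, n_sites=400, K=2, F=0.3, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
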