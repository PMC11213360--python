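import numpy as np
import pytest

import compocross as cc


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def counts_small(rng):
    """10 replicates x 5 features of modest random counts."""
    return rng.integers(0, 100, size=(10, 5))


@pytest.fixture(scope="session")
def caseb_cluster():
    """One case B dataset with a strong correlated cluster (c=0.2, rho=0.75)."""
    p, q = 30, 1
    psi = cc.cluster_correlation_matrix(p, q, c=0.2, rho=0.75, case="B")
    marg = cc.study_marginals(p, q, case="B")
    libs = cc.default_library_sizes("B")
    return cc.simulate_dataset(psi, marg, libs, n=100, case="B", q=q, seed=7)


@pytest.fixture(scope="session")
def casec_cluster():
    """One case C dataset with a correlated cluster across both datasets."""
    p = q = 30
    psi = cc.cluster_correlation_matrix(p, q, c=0.3, rho=0.75, case="C")
    marg = cc.study_marginals(p, q, case="C")
    libs = cc.default_library_sizes("C")
    return cc.simulate_dataset(psi, marg, libs, n=100, case="C", q=q, seed=11)
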