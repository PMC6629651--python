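import numpy as np
import pytest

import hire_ewas as h


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: deterministic and order-independent
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small K=3 alternative-scenario dataset for fast structural tests."""
    design = h.SimulationDesign(n=30, K=3, m=120, seed=5)
    return h.simulate_dataset(design)


@pytest.fixture(scope="session")
def small_params():
    """Random valid parameter set, m=3, n=4, K=2, q=1."""
    rng = np.random.default_rng(7)
    m, n, K, q = 3, 4, 2, 1
    return h.HireParams(
        P=rng.dirichlet(np.ones(K), n).T,
        mu=rng.uniform(0.2, 0.8, (m, K)),
        B=rng.normal(0, 0.05, (m, K, q)),
        Sigma=rng.uniform(0.002, 0.01, (m, K)),
        sigma_eps=rng.uniform(0.002, 0.01, m),
    )
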