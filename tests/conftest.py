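import numpy as np
import pytest

from straindec import seed_error_matrix
from straindec import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_recovery_sim():
    """G=3 strains, S=20 samples, V=100 variant positions, depth 50/site."""
    rng = np.random.default_rng(7)
    G, S, V = 3, 20, 100
    eps = seed_error_matrix(0.995)
    pi = sim.dirichlet_frequencies(G, S, rng)
    tau = sim.random_haplotypes(V, G, rng)
    tensor = sim.simulate_variant_tensor(tau, pi, eps, 50, rng)
    return {"tau": tau, "pi": pi, "eps": eps, "tensor": tensor, "G": G}
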