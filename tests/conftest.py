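import numpy as np
import pytest
import scipy.sparse as sp

from igem.synthdata import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with planted structure shared by read-only tests."""
    cfg = SimConfig(n_subjects=80, n_topics=3, n_genes=80, n_cpgs=100,
                    n_snps=120, n_genesets=12, frac_differential=0.2)
    return generate_cohort(cfg, seed=11)


def random_instance(rng, n=12, g=15, c=18, s=5, k=3, density=0.1):
    """A random consistent (X1, X2, rho, B) problem for model tests."""
    W = rng.gamma(2.0, 1.0, (n, k))
    alpha = rng.gamma(2.0, 1.0, (k, s))
    rho = rng.random((s, g))
    rho /= rho.sum(axis=1, keepdims=True)
    H2 = rng.gamma(2.0, 1.0, (k, c))
    X1 = W @ alpha @ rho + rng.random((n, g)) * 0.1
    X2 = W @ H2 + rng.random((n, c)) * 0.1
    B = sp.random(g, c, density, random_state=np.random.RandomState(rng.integers(2**31)),
                  format="csr")
    B.data[:] = 1.0
    return X1, X2, rho, B
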