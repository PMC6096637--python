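import numpy as np
import pytest

import recessmap as rm


@pytest.fixture(scope="session")
def two_group_cohort():
    """Two unadmixed, strongly differentiated groups (200 + 200)."""
    F = rm.sample_ancestral_frequencies(2000, divergence=0.3, seed=3)
    Q = np.zeros((400, 2))
    Q[:200, 0] = 1.0
    Q[200:, 1] = 1.0
    G = rm.sample_genotypes(Q, F, seed=4)
    return G, Q, F


@pytest.fixture(scope="session")
def small_admixed_cohort():
    """Admixed cohort for association smoke tests (n=300, m=500)."""
    G, pheno, model = rm.simulate_cohort(n=300, m=500, seed=11)
    return G, pheno, model
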