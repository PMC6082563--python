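import numpy as np
import pytest

import recckit as rk


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def two_group_mix():
    return rk.MixtureDistribution((0.5, 0.5), (0.0, 2.0))


@pytest.fixture
def three_group_mix():
    """Well-separated 3-group truth (zero-inflated motorway regime)."""
    return rk.MixtureDistribution.from_components(
        q=(0.17, 0.74, 0.082), lam=(0.0, 1.36, 3.4), window_years=2.0, normalise=True
    )


def random_mixture(rng, max_k=6, max_rate=10.0):
    """A random valid mixture for property tests."""
    k = int(rng.integers(1, max_k + 1))
    q = rng.dirichlet(np.ones(k))
    lam = np.sort(rng.uniform(0.0, max_rate, k))
    lam += np.arange(k) * 1e-6  # enforce strict increase
    return rk.MixtureDistribution.from_components(q, lam, normalise=True)
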