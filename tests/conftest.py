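import numpy as np
import pytest

from pleiosim import equicorrelation, simulate_dataset


@pytest.fixture(scope="session")
def pair_dataset():
    """Moderate-effect two-trait dataset reused by several method tests."""
    return simulate_dataset([0.005, 0.005], equicorrelation(2, 0.5),
                            n=2_000, maf=0.3, seed=11)


@pytest.fixture(scope="session")
def quad_dataset():
    """Four-trait dataset with mixed effects."""
    return simulate_dataset([0.005, 0.005, 0.001, 0.0], equicorrelation(4, 0.3),
                            n=2_000, maf=0.3, seed=13)


@pytest.fixture(scope="session")
def random_datasets():
    """A batch of random small datasets for equivalence checks."""
    rng = np.random.default_rng(42)
    out = []
    for i in range(100):
        k = int(rng.integers(2, 5))
        r = float(rng.uniform(-0.3, 0.8))
        v = rng.uniform(0.0, 0.01, size=k)
        out.append(simulate_dataset(v, equicorrelation(k, r), n=500,
                                    maf=float(rng.uniform(0.1, 0.5)), seed=100 + i))
    return out
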