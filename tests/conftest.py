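import numpy as np
import pandas as pd
import pytest

from multifun.diversity import OtuTable
from multifun.regression import build_spatial_weights
from multifun.synthetic import SimulationConfig, simulate_landscape


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_table():
    """3 taxa x 2 samples, hand-checkable."""
    return OtuTable(
        pd.DataFrame(
            [[5, 0], [0, 3], [1, 2]],
            index=["A", "B", "C"],
            columns=["s1", "s2"],
        )
    )


@pytest.fixture(scope="session")
def default_landscape():
    sites, functions, truth = simulate_landscape(SimulationConfig(seed=7))
    return sites, functions, truth


@pytest.fixture(scope="session")
def weights_400():
    """Shared 400-site weights matrix (eigenvalues cached on first use)."""
    rng = np.random.default_rng(5)
    coords = np.column_stack([rng.uniform(36, 44, 400), rng.uniform(-8, 4, 400)])
    return build_spatial_weights(coords, k=8)


def random_otu_table(rng, n_taxa=None, n_samples=None, max_count=50):
    n_taxa = n_taxa or int(rng.integers(2, 12))
    n_samples = n_samples or int(rng.integers(1, 6))
    counts = rng.integers(0, max_count, size=(n_taxa, n_samples))
    # ensure no empty sample
    for j in range(n_samples):
        if counts[:, j].sum() == 0:
            counts[rng.integers(0, n_taxa), j] = 1
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"T{i}" for i in range(n_taxa)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )
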