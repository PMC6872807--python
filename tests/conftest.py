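import numpy as np
import pandas as pd
import pytest

from varpp.experiments import make_study
from varpp.synthetic import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_matrix(rng, n_genes, n_cols, scale=100.0, prefix="S"):
    values = rng.uniform(0, scale, (n_genes, n_cols))
    return pd.DataFrame(
        values,
        index=[f"G{i:04d}" for i in range(n_genes)],
        columns=[f"{prefix}{j:02d}" for j in range(n_cols)],
    )


@pytest.fixture(scope="session")
def small_config():
    """A compact planted-signal study used across forest/spike-in tests."""
    return SyntheticConfig(
        n_genes=120,
        n_tissues=8,
        n_disease_genes=30,
        n_background_variants=120,
        n_background_genes=40,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    dataset, truth = make_study(small_config, np.random.default_rng(7))
    return dataset, truth
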