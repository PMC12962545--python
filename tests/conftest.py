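import numpy as np
import pandas as pd
import pytest

from mycofeedback.datasets import PipelineConfig
from mycofeedback.simulate import SimulationConfig, generate_full_dataset


@pytest.fixture(scope="session")
def small_sim_config():
    """Reduced study layout used where the full design is unnecessary."""
    return SimulationConfig(
        n_host_species=16,
        n_blocks=2,
        years=2,
        assay_species_per_study=6,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_sim_config):
    dataset, truth = generate_full_dataset(small_sim_config)
    return dataset, truth


@pytest.fixture(scope="session")
def default_dataset():
    """Full study-condition dataset (38 hosts, 4 blocks, 2 years)."""
    return generate_full_dataset(SimulationConfig(seed=7))


@pytest.fixture()
def pipeline_config():
    return PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_counts(rng, n_samples, n_features, lam=50.0):
    return pd.DataFrame(
        rng.poisson(lam, size=(n_samples, n_features)) + 1,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"f{j}" for j in range(n_features)],
    )
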