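import numpy as np
import pytest

from scamix import ExpressionDataset, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """Scaled-down synthetic study: 10 components, K=1500, 10+10 samples."""
    config = SimulationConfig(n_features=1500, n_disease=10, n_control=10, seed=2)
    dataset, truth = simulate_dataset(config)
    return config, dataset, truth


@pytest.fixture
def tiny_dataset():
    rng = np.random.default_rng(0)
    return ExpressionDataset(
        values=rng.normal(size=(6, 8)),
        feature_ids=[f"mz{j}" for j in range(8)],
        sample_ids=[f"s{i}" for i in range(6)],
        labels=np.array([1, 1, 1, -1, -1, -1]),
    )
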