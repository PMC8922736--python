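import numpy as np
import pytest

from degbench.core_data import ConditionLabels, CountMatrix
from degbench.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture
def toy_matrix() -> CountMatrix:
    counts = np.array(
        [
            [10, 20, 30, 40, 50],
            [0, 0, 0, 0, 0],
            [5, 15, 25, 35, 45],
            [100, 200, 300, 400, 500],
        ]
    )
    return CountMatrix(["g1", "g2", "g3", "g4"], ["s1", "s2", "s3", "s4", "s5"], counts)


@pytest.fixture
def toy_labels() -> ConditionLabels:
    return ConditionLabels(
        ["s1", "s2", "s3", "s4", "s5"], ["A", "A", "B", "A", "B"]
    )


def random_count_matrix(rng: np.random.Generator, n_genes=None, n_samples=None) -> CountMatrix:
    g = n_genes or int(rng.integers(2, 12))
    s = n_samples or int(rng.integers(2, 8))
    counts = rng.negative_binomial(2, 0.02, size=(g, s))
    return CountMatrix(
        [f"g{i}" for i in range(g)], [f"s{j}" for j in range(s)], counts
    )


@pytest.fixture(scope="session")
def small_null_parent():
    """Clean NB null dataset used by several calibration checks."""
    cfg = SimulationConfig(G=400, n1=30, n2=30, pi=0.0, epsilon=0.0, seed=20240)
    return simulate_dataset(cfg)
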