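import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from trophicweb import AnalysisConfig, InteractionMatrix
from trophicweb.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def example_matrix() -> InteractionMatrix:
    """The 2x2 worked example: counts [[2,0],[1,1]], hosts x parasitoids."""
    return InteractionMatrix("demo", ["h1", "h2"], ["q1", "q2"], [[2, 0], [1, 1]])


@pytest.fixture
def fast_config() -> AnalysisConfig:
    return AnalysisConfig(
        random_seed=0,
        n_null=199,
        n_perm_ordination=199,
        n_perm_parafit=199,
        n_extinction_orders=200,
        nmds_restarts=3,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset under default study conditions, shared read-only."""
    return simulate_dataset(SimulationConfig(seed=11))


def random_interaction_matrix(rng: np.random.Generator, max_dim: int = 6, max_count: int = 20):
    """Random small nonempty interaction matrix for oracle comparisons."""
    while True:
        i = int(rng.integers(1, max_dim + 1))
        j = int(rng.integers(1, max_dim + 1))
        counts = rng.integers(0, max_count + 1, size=(i, j))
        if counts.sum() >= 1:
            return InteractionMatrix(
                f"r{rng.integers(1 << 30)}",
                [f"h{k}" for k in range(i)],
                [f"q{k}" for k in range(j)],
                counts,
            )
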