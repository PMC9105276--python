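import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dormantx.experiment import make_experiment

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_experiment():
    """3 genes x 3 models, hand-set counts for exact-value checks."""
    counts = np.array([
        # m1_act m1_dor m2_act m2_dor m3_act m3_dor
        [100, 50, 100, 50, 100, 50],
        [10, 40, 10, 40, 10, 40],
        [2000, 2000, 2000, 2000, 2000, 2000],
    ])
    return make_experiment(counts, ["gA", "gB", "gC"],
                           ["m1", "m2", "m3"],
                           np.array([1000.0, 1000.0, 1000.0]))


@pytest.fixture
def random_experiment(rng):
    """20 genes x 5 models of positive random counts."""
    counts = rng.integers(1, 500, size=(20, 10))
    genes = [f"g{i:02d}" for i in range(20)]
    lengths = rng.uniform(300, 5000, size=20)
    return make_experiment(counts, genes,
                           [f"m{j}" for j in range(5)], lengths)
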