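import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_counts():
    """Six-sample, two-group count matrix for normalization tests."""
    from netkda import CountMatrix

    gen = np.random.default_rng(42)
    mu = gen.lognormal(3, 1.5, size=(50, 1)) * np.ones((50, 6))
    counts = gen.negative_binomial(5, 5 / (5 + mu))
    counts[:, 3] = counts[:, 3] * 3
    counts[0, 3] += 20000  # dominant spike in one sample
    return CountMatrix(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(50)],
        sample_ids=[f"s{j}" for j in range(6)],
        genotype=("A", "A", "A", "B", "B", "B"),
    )
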