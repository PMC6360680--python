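import numpy as np
import pytest

from bcrange import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    """A 20 x 6 table with two informative and four noise features."""
    n = 20
    y = np.array([0, 1] * (n // 2))
    X = rng.standard_normal((n, 6))
    X[:, 0] += 3.0 * y
    X[:, 1] -= 2.0 * y
    return FeatureTable(
        X=X,
        sample_ids=[f"s{i}" for i in range(n)],
        feature_ids=[f"f{j}" for j in range(6)],
        labels=y,
    )
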