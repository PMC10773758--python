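import numpy as np
import pytest

from efsgini import Dataset, make_synthetic, make_worked_example


@pytest.fixture(scope="session")
def worked():
    """The fixed 12 x 8 two-class worked example with oracle expectations."""
    ds, expected = make_worked_example()
    return ds, expected


@pytest.fixture()
def two_class_toy():
    """4 samples, 2 features: f0 separates classes perfectly, f1 does not."""
    X = np.array([[1.0, 5.0], [2.0, 1.0], [3.0, 4.0], [4.0, 2.0]])
    return Dataset(X, ["a", "a", "b", "b"], ["f0", "f1"], ["s1", "s2", "s3", "s4"])


@pytest.fixture(scope="session")
def small_synthetic():
    """A scaled-down planted-structure dataset for fast end-to-end tests."""
    ds, truth = make_synthetic(
        n_samples=100, n_features=300, n_informative=5,
        n_redundant_per_informative=1, n_classes=2, effect_size=2.0, seed=7,
    )
    return ds, truth


def random_labeled_matrix(rng, n, p, n_classes=2):
    """Random dataset with >= 1 sample per class (labels shuffled)."""
    y = [f"c{i % n_classes}" for i in range(n)]
    rng.shuffle(y)
    X = rng.normal(size=(n, p))
    return Dataset(X, y, [f"f{j}" for j in range(p)], [f"s{i}" for i in range(n)])
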