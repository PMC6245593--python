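import numpy as np
import pytest

from blasso.data_io import ExpressionDataset


def make_classification(n=50, p=5, seed=0, effect=1.5):
    """Random logistic instance with a few informative features."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    k = min(3, p)
    beta[:k] = np.array([effect, -effect, effect / 2])[:k]
    prob = 1.0 / (1.0 + np.exp(-(X @ beta)))
    y = (rng.random(n) < prob).astype(int)
    if y.min() == y.max():  # force both classes
        y[0] = 1 - y[0]
    return X, y


@pytest.fixture
def toy_dataset():
    """Deterministic 6-sample x 4-gene dataset with both classes."""
    rng = np.random.default_rng(11)
    X = rng.uniform(1.0, 10.0, size=(6, 4))
    return ExpressionDataset(
        matrix=X,
        gene_symbols=["TP53", "BRCA1", "EGFR", "MYC"],
        labels=np.array([0, 1, 0, 1, 1, 0]),
        sample_ids=[f"s{i}" for i in range(6)],
    )
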