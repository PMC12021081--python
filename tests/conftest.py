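import numpy as np
import pytest

from typemap.data import AnnotatedMatrix, FeaturePair


def random_softmax(rng, n, d):
    logits = rng.standard_normal((n, d)) * 2
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_matrix(rng):
    counts = rng.poisson(2.0, size=(30, 40))
    return AnnotatedMatrix(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(40)],
        cell_ids=[f"c{i}" for i in range(30)],
        batch=["b0"] * 15 + ["b1"] * 15,
        label=["A", "B", "C"] * 10,
    )


@pytest.fixture
def tiny_features(rng):
    """A minimal FeaturePair: 8 reference + 6 query cells, 5 genes, 3 types."""
    m, n, g, d = 8, 6, 5, 3
    return FeaturePair(
        ref_features=rng.standard_normal((m, g)),
        query_features=rng.standard_normal((n, g)),
        hvg_ids=[f"g{i}" for i in range(g)],
        batch_index=np.array([0] * m + [1] * n),
        n_batches=2,
        label_codes_ref=rng.integers(0, d, size=m),
        type_names=["A", "B", "C"],
    )
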