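import numpy as np
import pytest

from graphd import Graph, generate_codebook


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def triangle():
    return Graph.build(["A", "B", "C"], [("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def triangle_codebook():
    return generate_codebook(["A", "B", "C"], 10000, seed=7)


def random_bipolar(rng, *shape):
    """Independent bipolar draws for test oracles (not via the package)."""
    return (rng.integers(0, 2, size=shape, dtype=np.int64) * 2 - 1).astype(np.int64)
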