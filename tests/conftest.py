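import numpy as np
import pytest

from pollinet.network_io import BipartiteNetwork


def make_network(weights, quantitative=False, exotic=None, network_id="test"):
    w = np.asarray(weights, dtype=float)
    return BipartiteNetwork(
        plant_ids=tuple(f"P{i}" for i in range(w.shape[0])),
        pollinator_ids=tuple(f"A{j}" for j in range(w.shape[1])),
        weights=w,
        quantitative=quantitative,
        exotic=exotic,
        network_id=network_id,
    )


@pytest.fixture
def triangle3():
    """Strictly nested 3x3 triangle (row/column degrees 3, 2, 1)."""
    return make_network([[1, 1, 1], [1, 1, 0], [1, 0, 0]])


@pytest.fixture
def triangle4():
    """Strictly nested 4x4 triangle."""
    return make_network(
        [[1, 1, 1, 1], [1, 1, 1, 0], [1, 1, 0, 0], [1, 0, 0, 0]]
    )


@pytest.fixture
def small_quantitative():
    return make_network(
        [[3, 1, 0], [0, 2, 4], [5, 0, 1]],
        quantitative=True,
        exotic=[False, True, False],
    )


def random_connected_binary(rng, n_rows, n_cols, p=0.4, max_tries=200):
    """A random binary matrix with no empty rows or columns."""
    for _ in range(max_tries):
        m = (rng.random((n_rows, n_cols)) < p).astype(int)
        if m.sum(axis=1).min() > 0 and m.sum(axis=0).min() > 0:
            return m
    raise RuntimeError("could not draw a connected matrix")
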