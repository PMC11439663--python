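import numpy as np
import pytest

from pscdkit.connectivity import ConnectivityMatrix
from pscdkit.graphs import BinaryGraph


def graph_from_edges(n, edges):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryGraph(a, [f"n{i}" for i in range(n)])


def matrix_from_values(values, scale="pearson_r"):
    values = np.asarray(values, dtype=float)
    return ConnectivityMatrix(values, [f"n{i}" for i in range(len(values))], scale=scale)


@pytest.fixture
def triangle():
    return graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path3():
    return graph_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def star4():
    return graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])


@pytest.fixture
def triangle_pendant():
    return graph_from_edges(4, [(0, 1), (1, 2), (0, 2), (2, 3)])


@pytest.fixture
def two_cliques4():
    edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    edges += [(i + 4, j + 4) for i, j in edges]
    return graph_from_edges(8, edges)
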