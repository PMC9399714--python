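import numpy as np
import pandas as pd
import pytest

from rdpglink import BipartiteGraph, NodeMetadataTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_graph():
    # 4 x 3 toy graph, first-occurrence id order
    A = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0], [0, 0, 1]])
    return BipartiteGraph(["a", "b", "c", "d"], ["x", "y", "z"], A)


@pytest.fixture
def mixed_metadata():
    df = pd.DataFrame(
        {
            "kind": ["A", "B", "A", "C"],
            "lat": [0.0, 10.0, 5.0, 5.0],
            "lon": [2.0, 4.0, 6.0, 8.0],
        }
    )
    schema = {"kind": "categorical", "lat": "continuous", "lon": "continuous"}
    return NodeMetadataTable(["a", "b", "c", "d"], df, schema)


def random_graph(rng, M, N, density=0.3):
    A = (rng.random((M, N)) < density).astype(int)
    return BipartiteGraph(
        [f"r{i}" for i in range(M)], [f"c{j}" for j in range(N)], A
    )
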