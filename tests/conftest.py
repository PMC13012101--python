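import numpy as np
import pandas as pd
import pytest

from synpas.io import ExpressionMatrix, InteractionEdge, PNNode, ProteostasisNetwork


@pytest.fixture
def toy_network():
    """Six-gene network with mixed signs and a small edge set."""
    nodes = [
        PNNode("A", "promoter", +1, "first_degree"),
        PNNode("B", "promoter", +1, "first_degree"),
        PNNode("C", "attenuator", -1, "first_degree"),
        PNNode("D", "attenuator", -1, "first_degree"),
        PNNode("U1", None, +1, "upstream"),
        PNNode("U2", None, -1, "upstream"),
    ]
    edges = [
        InteractionEdge("A", "SNCA"),
        InteractionEdge("B", "SNCA"),
        InteractionEdge("C", "SNCA"),
        InteractionEdge("D", "SNCA"),
        InteractionEdge("A", "B"),
        InteractionEdge("U1", "A"),
        InteractionEdge("B", "U2", directed=False),
    ]
    return ProteostasisNetwork("SNCA", nodes, edges)


def random_network(rng: np.random.Generator, k: int) -> ProteostasisNetwork:
    """Random signed network without edges (scoring only)."""
    signs = rng.choice([-1, 1], size=k)
    nodes = [
        PNNode(f"G{i:03d}", "promoter" if s > 0 else "attenuator", int(s), "first_degree")
        for i, s in enumerate(signs)
    ]
    return ProteostasisNetwork("SNCA", nodes, [])


@pytest.fixture
def make_expression():
    def _make(values: dict, scale="log2", meta=None):
        df = pd.DataFrame(values).T  # rows genes
        return ExpressionMatrix(values=df, scale=scale, sample_meta=meta)
    return _make
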