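import pytest

from circuitsim import (
    Edge,
    ExpressionProfile,
    Node,
    PathwayGraph,
)


@pytest.fixture
def diamond_graph():
    """R -> A -> E, R -> B -> E (all activation)."""
    nodes = [Node(n, (n,)) for n in ("R", "A", "B", "E")]
    edges = [
        Edge("R", "A", "activation"),
        Edge("R", "B", "activation"),
        Edge("A", "E", "activation"),
        Edge("B", "E", "activation"),
    ]
    return PathwayGraph("diamond", "diamond", nodes, edges)


@pytest.fixture
def chain_graph():
    """R -> A -> E (all activation)."""
    nodes = [Node(n, (n,)) for n in ("R", "A", "E")]
    edges = [Edge("R", "A", "activation"), Edge("A", "E", "activation")]
    return PathwayGraph("chain", "chain", nodes, edges)


def make_profile(**values):
    return ExpressionProfile("test", dict(values))
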