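import itertools

import pytest

from kvotes import InteractionNetwork, NetworkEnsemble


def clique_edges(names):
    return list(itertools.combinations(names, 2))


@pytest.fixture
def toy_ensemble():
    """Three small networks with hand-countable votes:
    votes = {ab: 3, bc: 2, cd: 1, de: 1}."""
    return NetworkEnsemble(
        [
            InteractionNetwork("E1", [("a", "b"), ("b", "c")]),
            InteractionNetwork("E2", [("a", "b"), ("c", "d")]),
            InteractionNetwork("E3", [("a", "b"), ("b", "c"), ("d", "e")]),
        ]
    )


@pytest.fixture
def two_cliques():
    """Two disjoint 5-cliques: a0..a4 and b0..b4."""
    names_a = [f"a{i}" for i in range(5)]
    names_b = [f"b{i}" for i in range(5)]
    return InteractionNetwork(
        "cliques", clique_edges(names_a) + clique_edges(names_b)
    )


@pytest.fixture
def bridged_cliques(two_cliques):
    """Two 5-cliques plus a bridge vertex adjacent to 2 vertices of each."""
    edges = list(two_cliques.edges) + [
        ("h", "a0"), ("h", "a1"), ("h", "b0"), ("h", "b1")
    ]
    return InteractionNetwork("bridged", edges)
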