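import networkx as nx
import pytest

from setnet import BackgroundNetwork, GeneList, GeneSetLibrary


def gl(name, *genes):
    """Shorthand GeneList constructor for tests."""
    return GeneList(name=name, genes=tuple(genes))


@pytest.fixture
def six_node_net():
    """The worked expansion example: edges A-X, X-B, A-Y, Y-C, X-Z."""
    g = nx.Graph([("A", "X"), ("X", "B"), ("A", "Y"), ("Y", "C"), ("X", "Z")])
    return BackgroundNetwork(g)


@pytest.fixture
def abc_seeds():
    return gl("seeds", "A", "B", "C")


@pytest.fixture
def small_library():
    return GeneSetLibrary(
        "lib",
        [
            gl("S1", "A", "B", "C", "D"),
            gl("S2", "C", "D", "E"),
            gl("S3", "F", "G"),
        ],
    )


def network_from_edges(*edges):
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v)
    return BackgroundNetwork(g)
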