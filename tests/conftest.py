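import networkx as nx
import pytest

from airprio import fixtures as fx
from airprio.network import Edge, InteractionNetwork


@pytest.fixture(scope="session")
def characterizations():
    return fx.load_disease_characterizations()


@pytest.fixture(scope="session")
def char_by_id(characterizations):
    return {c.disease_id: c for c in characterizations}


@pytest.fixture(scope="session")
def disease_scores():
    return fx.load_disease_scores()


@pytest.fixture(scope="session")
def motif_scores():
    return fx.load_motif_scores()


@pytest.fixture(scope="session")
def candidate_panel():
    return fx.load_candidate_panel()


@pytest.fixture
def path_net():
    """a - b - c - d chain."""
    return InteractionNetwork(edges=[Edge("a", "b"), Edge("b", "c"), Edge("c", "d")])


def net_from_nx(g: nx.Graph) -> InteractionNetwork:
    return InteractionNetwork(
        edges=[Edge(str(a), str(b)) for a, b in g.edges],
        nodes=[str(n) for n in g.nodes],
    )
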