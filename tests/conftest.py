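import networkx as nx
import pytest

from metacore.kcore import decompose
from metacore.network import build_network
from metacore.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def truth3():
    """Three-species planted fixture at the default study conditions."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def nets3(truth3):
    return {
        sp: build_network(rxns, sp) for sp, rxns in truth3.reactions.items()
    }


@pytest.fixture(scope="session")
def decomps3(nets3):
    return {sp: decompose(G) for sp, G in nets3.items()}


@pytest.fixture()
def k5_pendant():
    """K5 with one pendant node: clique shells 4, pendant shell 1."""
    G = nx.complete_graph(5)
    G.add_edge(0, "pendant")
    return G


def random_graphs(n_graphs, max_n=60, seed0=0):
    """Seeded stream of small random graphs at mixed densities."""
    for i in range(n_graphs):
        n = 5 + (i * 7) % (max_n - 4)
        p = (0.05, 0.12, 0.25, 0.5)[i % 4]
        yield nx.gnp_random_graph(n, p, seed=seed0 + i)
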