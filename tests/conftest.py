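import random

import pytest

from pathcomplex.core import AssemblyObject
from pathcomplex import fixtures


@pytest.fixture(scope="session")
def named_strings():
    return dict(fixtures.NAMED)


@pytest.fixture
def rng():
    return random.Random(20170342)


def random_connected_graph(rng, n, classes="ab", p=0.5, directed=False):
    """Small random connected labeled graph as an AssemblyObject."""
    import networkx as nx

    while True:
        g = nx.gnp_random_graph(n, p, seed=rng.randint(0, 10 ** 6))
        if n == 1 or nx.is_connected(g):
            break
    cls = [rng.choice(classes) for _ in range(n)]
    return AssemblyObject.from_graph(
        [(i, cls[i]) for i in range(n)],
        [(u, v, "e") for u, v in g.edges()],
        directed=directed,
    )
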