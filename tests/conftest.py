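import itertools

import pytest

from shortloop.netio import Network


def complete_graph(labels) -> Network:
    return Network.from_edges(itertools.combinations(list(labels), 2))


@pytest.fixture
def k3():
    return complete_graph("ABC")


@pytest.fixture
def k4():
    return complete_graph("ABCD")


@pytest.fixture
def k5():
    return complete_graph("ABCDE")


@pytest.fixture
def fig_fan():
    """Two hubs X and Y sharing the chained partner pairs AB, BC, CD, with no
    X-Y interaction: the canonical commonality motif."""
    chain = ["A", "B", "C", "D"]
    edges = list(zip(chain, chain[1:]))
    for hub in ("X", "Y"):
        edges += [(hub, n) for n in chain]
    return Network.from_edges(edges)
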