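import numpy as np
import pytest

from etna.graph_io import network_from_edges


@pytest.fixture
def path_graph():
    """a - b - c."""
    return network_from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def small_net():
    """5 vertices, 6 edges; generic enough for loss/gradient tests."""
    return network_from_edges(
        [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("a", "c"), ("b", "e")]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
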