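import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def butterfly() -> nx.Graph:
    """Two triangles {1,2,3} and {3,4,5} sharing node 3."""
    return nx.Graph([(1, 2), (1, 3), (2, 3), (3, 4), (3, 5), (4, 5)])


@pytest.fixture
def four_clique() -> nx.Graph:
    return nx.complete_graph(4)
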