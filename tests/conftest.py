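import numpy as np
import pytest

from spillcast import (
    GraphTensors,
    Message,
    MessageStore,
    SocialGraph,
)
from spillcast.features import NodeAttributes


@pytest.fixture
def line_graph():
    """Mutual path a-b-c (follower edges in both directions)."""
    return SocialGraph.from_edges(
        [("a", "b"), ("b", "a"), ("b", "c"), ("c", "b")]
    )


@pytest.fixture
def small_graph():
    """8-node mutual graph with mixed degrees, for oracle comparisons."""
    rng = np.random.default_rng(42)
    edges = set()
    nodes = [f"n{i}" for i in range(8)]
    while len(edges) < 11:
        a, b = rng.choice(8, size=2, replace=False)
        edges.add((f"n{a}", f"n{b}"))
        edges.add((f"n{b}", f"n{a}"))
    return SocialGraph.from_edges(sorted(edges), nodes=nodes)


@pytest.fixture
def small_attrs(small_graph):
    gt = GraphTensors(small_graph)
    rng = np.random.default_rng(7)
    d_text, d_struct = 5, 3
    M = rng.standard_normal((gt.n, 1 + d_text + d_struct))
    return gt, NodeAttributes(nodes=gt.nodes, matrix=M, d_text=d_text, d_struct=d_struct)


@pytest.fixture
def retweet_store():
    """Root by u1 at t=0 with retweets by u2 (t=5) and u3 (t=3)."""
    return MessageStore(
        [
            Message(id="m0", author="u1", timestamp=0.0, text="root"),
            Message(id="m1", author="u2", timestamp=5.0, retweet_of="m0"),
            Message(id="m2", author="u3", timestamp=3.0, retweet_of="m0"),
        ]
    )
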