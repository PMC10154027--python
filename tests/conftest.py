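import numpy as np
import pytest

from metapom.network import ReactionRecord, build_network
from metapom.synthetic import GeneratorConfig, make_metabolome, make_embedding_table


@pytest.fixture(scope="session")
def small_met():
    """A 200-metabolite synthetic metabolome shared by read-only tests."""
    return make_metabolome(GeneratorConfig(seed=3, n_metabolites=200))


@pytest.fixture(scope="session")
def small_embedding(small_met):
    cfg = GeneratorConfig(seed=3, n_metabolites=200, rho=0.9)
    return make_embedding_table(small_met, cfg)


@pytest.fixture()
def chain_network():
    """A -> B -> C -> ... linear chain of 13 metabolites."""
    keys = [chr(ord("A") + i) for i in range(13)]
    reactions = [
        ReactionRecord(reaction_id=f"r{i}", reactants=(keys[i],), products=(keys[i + 1],))
        for i in range(12)
    ]
    return build_network(reactions), keys


def bfs_distances(edges, source):
    """Independent BFS oracle over a directed edge list."""
    from collections import deque

    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set())
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist
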