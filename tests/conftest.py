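import numpy as np
import pytest

from bitterqsar import read_smiles
from bitterqsar.synth import PlantedModelSpec, gen_descriptor_table


@pytest.fixture(scope="session")
def benzene():
    return read_smiles("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def phenol():
    return read_smiles("Oc1ccccc1", "phenol")


@pytest.fixture(scope="session")
def small_planted_table():
    """490-row planted table at default study conditions, fixed seed."""
    return gen_descriptor_table(PlantedModelSpec(seed=12345))


def bfs_distances(n_atoms, edges, source):
    """Independent BFS oracle used to cross-check shortest-path code."""
    adj = {k: [] for k in range(n_atoms)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def wiener_oracle(mol):
    """Half the sum of all BFS distances over heavy-atom pairs."""
    heavy = mol.heavy_indices()
    hset = set(heavy)
    edges = [(b.i, b.j) for b in mol.bonds if b.i in hset and b.j in hset]
    total = 0
    for s in heavy:
        d = bfs_distances(mol.n_atoms, edges, s)
        total += sum(v for k, v in d.items() if k in hset)
    assert total % 2 == 0
    return total // 2
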