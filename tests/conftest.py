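import numpy as np
import pytest

from molmae.molio import MolecularGraph, parse_smiles
from molmae.synthdata import FixtureSpec, generate_corpus


@pytest.fixture
def ethanol():
    return parse_smiles("CCO")


@pytest.fixture
def benzene():
    return parse_smiles("c1ccccc1")


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(FixtureSpec(n_molecules=24, seed=3))


def path_graph(n: int, dim_attrs: int = 2) -> MolecularGraph:
    """A featurized path graph 0-1-...-(n-1) with single-bond attributes."""
    src, dst = [], []
    for u in range(n - 1):
        src.extend((u, u + 1))
        dst.extend((u + 1, u))
    edge_index = np.array([src, dst], dtype=np.int64).reshape(2, -1)
    return MolecularGraph(
        smiles="X" * n,
        node_attrs=np.zeros((n, dim_attrs), dtype=np.int64),
        edge_index=edge_index,
        edge_attrs=np.zeros((edge_index.shape[1], 2), dtype=np.int64),
    )


def random_graph(rng: np.random.Generator, n_max: int = 10,
                 p_edge: float = 0.4) -> MolecularGraph:
    """A random undirected graph dressed as a MolecularGraph."""
    n = int(rng.integers(1, n_max + 1))
    src, dst = [], []
    for u in range(n):
        for v in range(u + 1, n):
            if rng.random() < p_edge:
                src.extend((u, v))
                dst.extend((v, u))
    edge_index = np.array([src, dst], dtype=np.int64).reshape(2, -1)
    node_attrs = np.stack([rng.integers(0, 20, size=n),
                           rng.integers(0, 4, size=n)], axis=1).astype(np.int64)
    return MolecularGraph("X" * n, node_attrs, edge_index,
                          np.zeros((edge_index.shape[1], 2), dtype=np.int64))


def permute_graph(graph: MolecularGraph,
                  perm: np.ndarray) -> MolecularGraph:
    """Relabel nodes: new index of old node i is perm[i]."""
    inv = np.argsort(perm)
    return MolecularGraph(
        smiles=graph.smiles,
        node_attrs=graph.node_attrs[inv],
        edge_index=perm[graph.edge_index],
        edge_attrs=graph.edge_attrs.copy(),
    )
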