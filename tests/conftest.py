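import numpy as np
import pytest

from dualflow import (
    AnnotatedNetwork,
    SyntheticSpec,
    fig3_toy,
    generate,
    partition_genes,
)


def random_network(rng: np.random.Generator, n: int, p: float = 0.25) -> AnnotatedNetwork:
    """Erdos-Renyi-style random test graph over letter-ish identifiers."""
    names = [f"n{i:03d}" for i in range(n)]
    edges = [
        (names[i], names[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return AnnotatedNetwork.from_edges(edges, nodes=names)


@pytest.fixture(scope="session")
def path_graph():
    return AnnotatedNetwork.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture(scope="session")
def toy():
    net, roles = fig3_toy()
    return net, roles


@pytest.fixture(scope="session")
def small_bench():
    """A small planted-structure instance for fast end-to-end tests."""
    spec = SyntheticSpec(n_nodes=400, n_diseases=3, module_size=5, n_essentials=40, seed=7)
    net, gene_map, essentials, positions = generate(spec)
    disease = {g for gs in gene_map.values() for g in gs}
    part = partition_genes(net, disease, essentials)
    return net, gene_map, part, positions


@pytest.fixture(scope="session")
def bench2000():
    """The default benchmark instance (2000 nodes, 5 diseases x 6 genes)."""
    spec = SyntheticSpec(seed=0)
    net, gene_map, essentials, positions = generate(spec)
    disease = {g for gs in gene_map.values() for g in gs}
    part = partition_genes(net, disease, essentials)
    return net, gene_map, part, positions
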