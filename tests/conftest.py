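import random

import pytest

from coexnet.io import GeneNetwork


def random_network(rng: random.Random, species_id: str = "sp", max_nodes: int = 50,
                   edge_prob: float = 0.12) -> GeneNetwork:
    """Erdos-Renyi-style random gene network, possibly with isolated nodes."""
    n = rng.randint(2, max_nodes)
    genes = [f"{species_id}_g{i}" for i in range(n)]
    net = GeneNetwork(species_id)
    for g in genes:
        net.add_node(g)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                net.add_edge(genes[i], genes[j])
    return net


def random_family_map(rng: random.Random, genes, n_families: int = 8,
                      unmapped_frac: float = 0.2) -> dict[str, str]:
    fam = {}
    for g in genes:
        if rng.random() < unmapped_frac:
            continue
        fam[g] = f"FAM{rng.randint(1, n_families):03d}"
    return fam


@pytest.fixture
def rng():
    return random.Random(20240917)
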