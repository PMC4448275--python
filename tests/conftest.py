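import numpy as np
import networkx as nx
import pytest
from hypothesis import settings

from mvsim.config import NetworkConfig
from mvsim.motifs import GENE, MIRNA
from mvsim.topology import DegreeState, build_network, sample_degree_targets

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=20)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_network():
    """A reproducible 60-node network with miRNAs and signals."""
    return build_network(NetworkConfig(n_genes=50, n_mirnas=10, n_signals=3, seed=11))


def random_tiny_graph(rng, n_genes, n_mirnas, edge_prob=0.3):
    """A random typed digraph plus matching targets/state for score oracles."""
    g = nx.DiGraph()
    for i in range(n_genes):
        g.add_node(f"g{i}", kind=GENE)
    for i in range(n_mirnas):
        g.add_node(f"m{i}", kind=MIRNA)
    nodes = list(g.nodes)
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < edge_prob:
                g.add_edge(u, v, sign="activation")
    config = NetworkConfig(n_genes=n_genes, n_mirnas=n_mirnas)
    targets = sample_degree_targets(config)
    state = DegreeState.from_network(g)
    return g, targets, state
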