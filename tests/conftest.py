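import networkx as nx
import numpy as np
import pytest

from coregnet.netbuild import RegulatoryNetwork
from coregnet.simdata import SimConfig, simulate_counts, simulate_interaction_db


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_genes=300, n_tfs=30, n_mirnas=15, n_per_group=6, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    db = simulate_interaction_db(small_config)
    cm, truth = simulate_counts(small_config, db=db)
    return cm, truth, db


def make_network(edges, extra_nodes=(), node_types=None) -> RegulatoryNetwork:
    """Build a RegulatoryNetwork from (src, tgt) or (src, tgt, type) tuples."""
    g = nx.DiGraph()
    for e in edges:
        src, tgt = e[0], e[1]
        etype = e[2] if len(e) > 2 else "TF->gene"
        g.add_edge(src, tgt, edge_type=etype)
    for v in extra_nodes:
        g.add_node(v)
    for v in g.nodes:
        g.nodes[v].setdefault("node_type", (node_types or {}).get(v, "gene"))
    return RegulatoryNetwork(graph=g)


def random_digraph(n: int, p: float, seed: int) -> RegulatoryNetwork:
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    nodes = [f"n{i:02d}" for i in range(n)]
    g.add_nodes_from(nodes)
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                g.add_edge(nodes[i], nodes[j], edge_type="TF->gene")
    for v in g.nodes:
        g.nodes[v]["node_type"] = "gene"
    return RegulatoryNetwork(graph=g)
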