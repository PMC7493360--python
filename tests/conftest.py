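import random

import networkx as nx
import pytest

from nautica.network import PPINetwork


@pytest.fixture
def write_tsv(tmp_path):
    """Write tab-separated lines to a temp file and return its path."""

    def _write(name, lines):
        path = tmp_path / name
        path.write_text("\n".join("\t".join(map(str, row)) for row in lines) + "\n")
        return path

    return _write


@pytest.fixture
def small_net():
    """Edges {A-C, B-C, A-D, B-D, A-B, A-E}: shared(A,B)=2, shared(A,E)=0."""
    g = nx.Graph()
    g.add_edges_from([("A", "C"), ("B", "C"), ("A", "D"),
                      ("B", "D"), ("A", "B"), ("A", "E")])
    return PPINetwork(graph=g)


def random_network(seed, n_nodes, edge_prob=0.1):
    """Erdos-Renyi PPINetwork with string node names."""
    rng = random.Random(seed)
    g = nx.Graph()
    names = [f"N{i:03d}" for i in range(n_nodes)]
    g.add_nodes_from(names)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                g.add_edge(names[i], names[j])
    return PPINetwork(graph=g)
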