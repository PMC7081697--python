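"""Shared fixtures: small hand-built networks and file writers."""

from pathlib import Path

import pytest

from targo.network import assemble_network, build_transition_operator


def write_edges(path: Path, pairs, header: str = "# test edges") -> Path:
    lines = [header] + [f"{a}\t{b}" for a, b in pairs]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def edge_writer(tmp_path):
    def _write(name, pairs):
        return write_edges(tmp_path / name, pairs)
    return _write


@pytest.fixture
def cycle3(edge_writer):
    """Directed 3-cycle A->B->C->A (pathway provenance, directed)."""
    path = edge_writer("cycle.tsv", [("A", "B"), ("B", "C"), ("C", "A")])
    net = assemble_network([(path, "pathway")])
    return net, build_transition_operator(net)


@pytest.fixture
def star_with_dangling(edge_writer):
    """X->A, X->B, A->Y; Y dangling; 4 nodes (directed pathway edges)."""
    path = edge_writer("star.tsv", [("X", "A"), ("X", "B"), ("A", "Y")])
    net = assemble_network([(path, "pathway")])
    return net, build_transition_operator(net)


def random_directed_network(rng, n, p=0.3):
    """Random directed network built directly (no files) for oracle tests."""
    from targo.network import GeneNetwork
    width = len(str(n))
    nodes = tuple(f"n{i:0{width}d}" for i in range(n))
    edges = set()
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                edges.add((nodes[i], nodes[j], "pathway"))
    if not edges:
        edges.add((nodes[0], nodes[-1], "pathway"))
    return GeneNetwork(nodes=nodes, edges=frozenset(edges),
                       node_index={g: i for i, g in enumerate(nodes)})
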