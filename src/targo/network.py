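"""Merged gene interaction network and its stochastic transition operator.

A network is assembled from provenance-tagged edge lists (protein-protein
interaction, curated pathway, co-expression).  Edges from symmetric
evidence types are expanded to both directions; duplicates across sources
collapse to a single directed edge so that the 1/out-degree normalization
is not distorted by multiply-reported interactions.

The transition operator is the standard random-surfer construction: the
hyperlink matrix H holds 1/out-degree(i) in row i for every neighbor of i,
and rows of genes with no outgoing edges (dangling nodes) are replaced by
the uniform distribution 1/n, so that Pr = H + D is row-stochastic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

PROVENANCES = ("ppi", "pathway", "coexpression")

#: evidence types treated as symmetric by default
DEFAULT_UNDIRECTED = frozenset({"ppi", "coexpression"})


class EdgeFileError(ValueError):
    """Raised for unreadable or malformed edge-list input."""


@dataclass(frozen=True)
class GeneNetwork:
    """Merged directed interaction graph with per-edge provenance.

    Attributes
    ----------
    nodes : tuple of str
        Gene identifiers in deterministic (lexicographic) order; the
        position of a gene here is its matrix index.
    edges : frozenset of (source, target, provenance)
        Directed edges after symmetrization and duplicate collapse.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str, str]]
    node_index: Mapping[str, int] = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def directed_edges(self) -> frozenset[tuple[str, str]]:
        """Provenance-collapsed directed edges (an edge in two sources counts once)."""
        return frozenset((s, t) for s, t, _ in self.edges)

    def out_degree(self, gene: str) -> int:
        """Number of distinct outgoing neighbors over all provenances."""
        return sum(1 for s, _ in self.directed_edges if s == gene)

    def out_degrees(self) -> np.ndarray:
        """Vector of out-degrees in node order."""
        deg = np.zeros(self.n, dtype=np.int64)
        for s, _ in self.directed_edges:
            deg[self.node_index[s]] += 1
        return deg

    def total_degrees(self) -> np.ndarray:
        """Distinct-neighbor degree after symmetrization (for the hub diagnostic)."""
        neigh: dict[int, set[int]] = {i: set() for i in range(self.n)}
        for s, t in self.directed_edges:
            i, j = self.node_index[s], self.node_index[t]
            neigh[i].add(j)
            neigh[j].add(i)
        return np.array([len(neigh[i]) for i in range(self.n)], dtype=np.int64)

    def summary(self) -> pd.DataFrame:
        """Node/edge census with per-provenance counts and pairwise/3-way overlaps.

        The interaction count is directed (provenance-collapsed);
        per-provenance counts and overlaps are on unordered gene pairs,
        so a shared interaction counts once regardless of symmetrization.
        """
        rows: list[tuple[str, int]] = [("genes", self.n),
                                       ("interactions", len(self.directed_edges))]
        by_prov: dict[str, set] = {p: set() for p in PROVENANCES}
        for s, t, p in self.edges:
            by_prov[p].add((min(s, t), max(s, t)))
        for p in PROVENANCES:
            rows.append((f"edges_{p}", len(by_prov[p])))
        for i, p in enumerate(PROVENANCES):
            for q in PROVENANCES[i + 1:]:
                rows.append((f"overlap_{p}_{q}", len(by_prov[p] & by_prov[q])))
        rows.append(("overlap_3way",
                     len(by_prov["ppi"] & by_prov["pathway"] & by_prov["coexpression"])))
        return pd.DataFrame(rows, columns=["quantity", "count"])


@dataclass(frozen=True)
class TransitionOperator:
    """Row-stochastic random-walk operator Pr = H + D.

    H is the sparse hyperlink matrix (row i: 1/out-degree(i) on each
    neighbor), D fills dangling rows with the uniform value 1/n.  The
    dangling part is never materialized; :meth:`propagate` applies it as a
    rank-one correction.
    """

    H: sp.csr_matrix = field(repr=False)
    dangling_mask: np.ndarray = field(repr=False)
    n: int

    @property
    def dangling_value(self) -> float:
        return 1.0 / self.n

    def dangling_nodes(self, net: GeneNetwork) -> set[str]:
        return {net.nodes[i] for i in np.flatnonzero(self.dangling_mask)}

    def propagate(self, x: np.ndarray) -> np.ndarray:
        """Return x·Pr for a probability row-vector x."""
        y = x @ self.H
        dangling_mass = float(x[self.dangling_mask].sum())
        if dangling_mass:
            y = y + dangling_mass / self.n
        return np.asarray(y).ravel()

    def dense(self) -> np.ndarray:
        """Dense Pr, for small-n oracles and inspection only."""
        pr = self.H.toarray()
        pr[self.dangling_mask, :] = 1.0 / self.n
        return pr


def _read_edge_file(path: Path, provenance: str) -> list[tuple[str, str]]:
    if provenance not in PROVENANCES:
        raise EdgeFileError(
            f"unknown provenance {provenance!r}; expected one of {PROVENANCES}")
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise EdgeFileError(f"cannot read edge file {path}: {exc}") from exc
    pairs: list[tuple[str, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise EdgeFileError(
                f"{path}: malformed line {lineno}: need source<TAB>target, got {line!r}")
        pairs.append((fields[0].strip(), fields[1].strip()))
    return pairs


def assemble_network(
    edge_files: Sequence[tuple[str | Path, str]],
    undirected_provenances: Iterable[str] = DEFAULT_UNDIRECTED,
) -> GeneNetwork:
    """Merge provenance-tagged edge lists into a single directed network.

    Parameters
    ----------
    edge_files
        ``(path, provenance)`` pairs; provenance is one of ``ppi``,
        ``pathway``, ``coexpression``.  Files are tab-separated with at
        least two columns (source, target); ``#`` lines are skipped.
    undirected_provenances
        Evidence types whose edges are expanded to both directions.

    Self-loops are dropped and duplicate (source, target, provenance)
    triples are collapsed.
    """
    undirected = set(undirected_provenances)
    edges: set[tuple[str, str, str]] = set()
    for path, prov in edge_files:
        for s, t in _read_edge_file(Path(path), prov):
            if s == t:  # self-loop would feed a gene's own rank
                continue
            edges.add((s, t, prov))
            if prov in undirected:
                edges.add((t, s, prov))
    if not edges:
        raise EdgeFileError("no edges loaded")
    nodes = tuple(sorted({g for s, t, _ in edges for g in (s, t)}))
    net = GeneNetwork(nodes=nodes, edges=frozenset(edges),
                      node_index={g: i for i, g in enumerate(nodes)})
    logger.info("assembled network: %d genes, %d interactions",
                net.n, len(net.directed_edges))
    return net


def build_transition_operator(net: GeneNetwork) -> TransitionOperator:
    """Build Pr = H + D for a network with at least one node."""
    if net.n == 0:
        raise ValueError("network has no nodes")
    deg = net.out_degrees()
    rows, cols, vals = [], [], []
    for s, t in net.directed_edges:
        i = net.node_index[s]
        rows.append(i)
        cols.append(net.node_index[t])
        vals.append(1.0 / deg[i])
    H = sp.csr_matrix((vals, (rows, cols)), shape=(net.n, net.n))
    return TransitionOperator(H=H, dangling_mask=deg == 0, n=net.n)
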