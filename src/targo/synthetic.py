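"""Synthetic benchmark generator with planted structure.

Emits the exact artifacts the rest of the package consumes — three
provenance-tagged edge TSVs, a GMT signature file, and a known-association
label TSV — with ground truth recorded alongside, so the full pipeline is
testable without any database download.

The generator plants:

* a base interaction graph (Erdős–Rényi or Barabási–Albert, the latter
  for heavy-tailed degrees so the hub diagnostic is meaningful);
* per-term signature modules: the signature genes plus a fringe of
  "associated" neighbors, wired together with extra edge probability
  ``wiring_strength`` — the signal the ranking should recover;
* a controlled number of edges shared by all three provenance files;
* dangling nodes (no outgoing edges after the merge) and explicit hubs;
* a few sub-threshold terms whose network support is deliberately below
  the min-support filter.

Labels mark the planted associated genes, optionally flipped at a noise
rate.  Identical spec + seed reproduces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from targo.network import PROVENANCES


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; defaults are the package's benchmark scale."""

    n_genes: int = 500
    edge_model: str = "er"          # "er" | "ba"
    er_mean_degree: float = 6.0
    ba_m: int = 3
    n_terms: int = 30
    genes_per_term: int = 20
    fringe_per_term: int = 10       # wired neighbors counted as associated
    wiring_strength: float = 0.3    # extra within-module edge probability
    label_noise: float = 0.0
    n_shared_edges: int = 100       # planted in all three provenance files
    n_dangling: int = 5
    n_hubs: int = 3
    hub_degree: int = 50
    n_subthreshold_terms: int = 3
    subthreshold_genes: int = 8
    panel_terms: int = 0            # first terms share planted panel genes
    panel_genes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_terms", "genes_per_term"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("wiring_strength", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.edge_model not in ("er", "ba"):
            raise ValueError("edge_model must be 'er' or 'ba'")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth consistent with the emitted files."""

    signature_genes: dict[str, frozenset[str]]
    associated_genes: dict[str, frozenset[str]]     # signature + wired fringe
    panel_genes: frozenset[str]     # genes planted across the panel terms
    panel_terms: frozenset[str]
    subthreshold_terms: frozenset[str]
    dangling_nodes: frozenset[str]
    hub_nodes: frozenset[str]
    shared_edges: frozenset[tuple[str, str]]

    def manifest(self) -> pd.DataFrame:
        rows = []
        for term in sorted(self.signature_genes):
            for g in sorted(self.signature_genes[term]):
                rows.append((term, g, "signature"))
            for g in sorted(self.associated_genes[term] - self.signature_genes[term]):
                rows.append((term, g, "fringe"))
        for g in sorted(self.dangling_nodes):
            rows.append(("-", g, "dangling"))
        for g in sorted(self.hub_nodes):
            rows.append(("-", g, "hub"))
        return pd.DataFrame(rows, columns=["term_id", "gene", "role"])


@dataclass(frozen=True)
class SyntheticData:
    """Paths of everything one simulation emitted, plus the truth."""

    edge_files: tuple[tuple[Path, str], ...]
    gmt_path: Path
    label_path: Path
    truth_path: Path
    truth: SyntheticTruth = field(repr=False)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def generate_network(spec: SyntheticSpec, outdir: str | Path
                     ) -> tuple[list[tuple[Path, str]], SyntheticTruth]:
    """Emit three provenance edge TSVs; return their paths and the truth.

    Raises ``ValueError`` when the requested shared-edge count exceeds the
    number of planted edges.
    """
    rng = np.random.default_rng(spec.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = _gene_names(spec.n_genes)

    dangling = sorted(rng.choice(genes, size=spec.n_dangling, replace=False))
    walkers = sorted(set(genes) - set(dangling))   # genes allowed out-edges
    widx = {g: i for i, g in enumerate(walkers)}

    # --- base graph over the walker genes ---
    gseed = int(rng.integers(2**31 - 1))
    if spec.edge_model == "er":
        p = min(1.0, spec.er_mean_degree / max(1, len(walkers) - 1))
        G = nx.gnp_random_graph(len(walkers), p, seed=gseed)
    else:
        G = nx.barabasi_albert_graph(len(walkers), spec.ba_m, seed=gseed)
    edges: set[tuple[str, str]] = set()
    for i, j in G.edges():
        a, b = walkers[i], walkers[j]
        edges.add((min(a, b), max(a, b)))
    # keep every walker in the network
    for g in walkers:
        if G.degree(widx[g]) == 0:
            other = walkers[int(rng.integers(len(walkers)))]
            if other != g:
                edges.add((min(g, other), max(g, other)))

    # --- explicit hubs ---
    hubs = sorted(rng.choice(walkers, size=spec.n_hubs, replace=False))
    for h in hubs:
        targets = rng.choice(walkers, size=spec.hub_degree, replace=False)
        for t in targets:
            if t != h:
                edges.add((min(h, t), max(h, t)))

    # --- planted signature modules ---
    if spec.panel_genes > spec.genes_per_term:
        raise ValueError("panel_genes cannot exceed genes_per_term")
    # panel genes must be enriched in the panel terms only: keep them out
    # of the hub set and out of every non-panel module
    non_hub = sorted(set(walkers) - set(hubs))
    panel_pool = sorted(rng.choice(non_hub, size=spec.panel_genes,
                                   replace=False)) if spec.panel_genes else []
    background_pool = sorted(set(walkers) - set(panel_pool))
    signature: dict[str, frozenset[str]] = {}
    associated: dict[str, frozenset[str]] = {}
    panel_term_ids: list[str] = []
    for k in range(spec.n_terms):
        term = f"MP:SYN{k:04d}"
        if k < spec.panel_terms:
            # panel terms share the planted panel genes in their signature
            panel_term_ids.append(term)
            rest = sorted(set(walkers) - set(panel_pool))
            extra = sorted(rng.choice(
                rest, size=spec.genes_per_term - len(panel_pool)
                + spec.fringe_per_term, replace=False))
            module = sorted(panel_pool
                            + extra[:spec.genes_per_term - len(panel_pool)]) \
                + extra[spec.genes_per_term - len(panel_pool):]
        else:
            module = sorted(rng.choice(
                background_pool,
                size=spec.genes_per_term + spec.fringe_per_term,
                replace=False))
        sig = frozenset(module[:spec.genes_per_term])
        signature[term] = sig
        associated[term] = frozenset(module)
        for i, a in enumerate(module):
            for b in module[i + 1:]:
                if rng.random() < spec.wiring_strength:
                    edges.add((min(a, b), max(a, b)))
    sub_terms = []
    for k in range(spec.n_subthreshold_terms):
        term = f"MP:SUB{k:04d}"
        sub_terms.append(term)
        sig = frozenset(sorted(rng.choice(
            background_pool, size=spec.subthreshold_genes, replace=False)))
        signature[term] = sig
        associated[term] = sig

    if spec.n_shared_edges > len(edges):
        raise ValueError(
            f"requested {spec.n_shared_edges} shared edges but only "
            f"{len(edges)} edges were planted")

    # --- distribute edges across provenances ---
    edge_list = sorted(edges)
    shared_idx = set(rng.choice(len(edge_list), size=spec.n_shared_edges,
                                replace=False).tolist())
    prov_of = rng.integers(0, 3, size=len(edge_list))
    by_prov: dict[str, list[tuple[str, str]]] = {p: [] for p in PROVENANCES}
    shared: set[tuple[str, str]] = set()
    for idx, e in enumerate(edge_list):
        if idx in shared_idx:
            shared.add(e)
            for p in PROVENANCES:
                by_prov[p].append(e)
        else:
            by_prov[PROVENANCES[prov_of[idx]]].append(e)

    # dangling nodes get one incoming pathway edge each, so they are part
    # of the network with out-degree 0 after the merge
    dangling_in = []
    for g in dangling:
        src = walkers[int(rng.integers(len(walkers)))]
        dangling_in.append((src, g))

    paths: list[tuple[Path, str]] = []
    for prov in PROVENANCES:
        path = outdir / f"edges_{prov}.tsv"
        lines = [f"# synthetic {prov} edges"]
        if prov == "pathway":
            # pathway edges are consumed as directed: write both directions
            for a, b in by_prov[prov]:
                lines.append(f"{a}\t{b}")
                lines.append(f"{b}\t{a}")
            for s, g in dangling_in:
                lines.append(f"{s}\t{g}")
        else:
            for a, b in by_prov[prov]:
                lines.append(f"{a}\t{b}")
        path.write_text("\n".join(lines) + "\n")
        paths.append((path, prov))

    truth = SyntheticTruth(
        signature_genes=signature, associated_genes=associated,
        panel_genes=frozenset(panel_pool),
        panel_terms=frozenset(panel_term_ids),
        subthreshold_terms=frozenset(sub_terms),
        dangling_nodes=frozenset(dangling), hub_nodes=frozenset(hubs),
        shared_edges=frozenset(shared))
    return paths, truth


def generate_signatures_and_labels(
    spec: SyntheticSpec, truth: SyntheticTruth, outdir: str | Path
) -> tuple[Path, Path]:
    """Emit the GMT signature file and the known-association label TSV.

    Labels cover every (main term, gene) pair: 1 for planted associated
    genes, 0 otherwise, each flipped independently with probability
    ``label_noise``.  Sub-threshold terms appear in the GMT (they exist to
    exercise the support filter) but carry no labels.
    """
    rng = np.random.default_rng(spec.seed + 1)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = _gene_names(spec.n_genes)

    gmt_path = outdir / "signatures.gmt"
    lines = []
    for term in sorted(truth.signature_genes):
        gs = "\t".join(sorted(truth.signature_genes[term]))
        lines.append(f"{term}\tsynthetic signature {term}\t{gs}")
    gmt_path.write_text("\n".join(lines) + "\n")

    label_path = outdir / "labels.tsv"
    rows = ["term_id\tgene\tlabel"]
    main_terms = sorted(set(truth.signature_genes) - truth.subthreshold_terms)
    for term in main_terms:
        assoc = truth.associated_genes[term]
        flips = rng.random(len(genes)) < spec.label_noise
        for g, flip in zip(genes, flips):
            lab = int(g in assoc) ^ int(flip)
            rows.append(f"{term}\t{g}\t{lab}")
    label_path.write_text("\n".join(rows) + "\n")
    return gmt_path, label_path


def simulate(spec: SyntheticSpec, outdir: str | Path) -> SyntheticData:
    """Run the full generator and write the truth manifest."""
    outdir = Path(outdir)
    edge_files, truth = generate_network(spec, outdir)
    gmt_path, label_path = generate_signatures_and_labels(spec, truth, outdir)
    truth_path = outdir / "truth.tsv"
    truth.manifest().to_csv(truth_path, sep="\t", index=False)
    return SyntheticData(edge_files=tuple(edge_files), gmt_path=gmt_path,
                         label_path=label_path, truth_path=truth_path,
                         truth=truth)


def load_labels(path: str | Path) -> pd.DataFrame:
    """Read a label TSV (term_id, gene, label) into a long-format frame."""
    df = pd.read_csv(path, sep="\t", dtype={"term_id": str, "gene": str})
    if not set(df["label"].unique()) <= {0, 1}:
        raise ValueError("labels must be 0 or 1")
    return df
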