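"""Phenotype/disease signature gene sets and personalization vectors.

A signature set is the list of genes annotated to one phenotype or
disease term (MP- or MeSH-style identifier), read from standard GMT
files.  The per-term personalization (weight) vector pa places 1/|t_j| on
each signature gene present in the network and 0 elsewhere, so it is a
probability distribution over network genes and can serve as the teleport
vector of the topic-sensitive PageRank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from targo.network import GeneNetwork

logger = logging.getLogger(__name__)


class GMTError(ValueError):
    """Raised for malformed GMT input."""


@dataclass(frozen=True)
class SignatureSet:
    term_id: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature set {self.term_id} has no genes")


@dataclass(frozen=True)
class WeightVector:
    """Teleport distribution for one term, restricted to network genes."""

    term_id: str
    pa: np.ndarray = field(repr=False)  # indexed like net.nodes
    support_size: int

    def support(self, net: GeneNetwork) -> set[str]:
        return {net.nodes[i] for i in np.flatnonzero(self.pa)}


def load_signatures(path: str | Path) -> list[SignatureSet]:
    """Parse a GMT file (``term<TAB>description<TAB>gene1<TAB>gene2...``).

    Duplicate genes within a line are deduplicated; a duplicate term id
    across lines is an error.
    """
    sigs: list[SignatureSet] = []
    seen: set[str] = set()
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise GMTError(f"cannot read GMT file {path}: {exc}") from exc
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = [f for f in line.rstrip("\n").split("\t")]
        if len(fields) < 3:
            raise GMTError(f"{path}: line {lineno}: GMT needs term, description "
                           f"and at least one gene ({len(fields)} fields found)")
        term, desc = fields[0], fields[1]
        genes = frozenset(g for g in fields[2:] if g)
        if term in seen:
            raise GMTError(f"{path}: duplicate term {term!r} at line {lineno}")
        seen.add(term)
        sigs.append(SignatureSet(term_id=term, description=desc, genes=genes))
    return sigs


def build_weight_vector(sig: SignatureSet, net: GeneNetwork) -> WeightVector:
    """Uniform 1/|t_j| weights on the term's network-supported signature genes.

    |t_j| counts only signature genes present in the network, so the
    vector always sums to 1 and teleport mass never leaks to genes the
    walk cannot visit.
    """
    idx = [net.node_index[g] for g in sig.genes if g in net.node_index]
    if not idx:
        raise ValueError(f"term {sig.term_id} has no signature genes in network")
    pa = np.zeros(net.n)
    pa[idx] = 1.0 / len(idx)
    return WeightVector(term_id=sig.term_id, pa=pa, support_size=len(idx))


def filter_terms(
    sigs: list[SignatureSet],
    net: GeneNetwork,
    min_support: int = 10,
) -> list[SignatureSet]:
    """Keep terms with strictly more than ``min_support`` genes in the network.

    Idempotent; each keep/drop decision is logged.
    """
    kept: list[SignatureSet] = []
    for sig in sigs:
        support = sum(1 for g in sig.genes if g in net.node_index)
        if support > min_support:
            kept.append(sig)
            logger.debug("term %s kept (support %d)", sig.term_id, support)
        else:
            logger.info("term %s dropped (support %d <= %d)",
                        sig.term_id, support, min_support)
    return kept


def filter_log(sigs: list[SignatureSet], net: GeneNetwork,
               min_support: int = 10) -> pd.DataFrame:
    """Tabular version of the filtering decision (term, support, kept)."""
    rows = []
    for sig in sigs:
        support = sum(1 for g in sig.genes if g in net.node_index)
        rows.append((sig.term_id, support, support > min_support))
    return pd.DataFrame(rows, columns=["term_id", "support", "kept"])
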