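"""Multi-phenotype candidate selection by Fisher exact test with FDR control.

Given per-term TrustRank tables and a user-selected phenotype panel, each
gene is scored for enrichment of "top-ranked" status (trust rank within
the top fraction of the term's gene list) among panel terms versus the
background terms.  The 2x2 table for a gene is

                    top-ranked   not top-ranked
    panel term           a             b
    background term      c             d

tested one-sided for enrichment; Benjamini-Hochberg q-values control the
FDR and genes with q below the threshold (default 0.01) are selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from targo.ranking import RankResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionResult:
    """Per-gene Fisher table, p, BH q, and the q < fdr_threshold flag."""

    table: pd.DataFrame = field(repr=False)
    fdr_threshold: float
    selected: tuple[str, ...]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_gene_panel(
    results: list[RankResult],
    selected_terms: set[str],
    top_fraction: float = 0.05,
    fdr_threshold: float = 0.01,
    universe_terms: set[str] | None = None,
) -> SelectionResult:
    """Enrichment of top-ranked status among a panel of phenotype terms.

    Parameters
    ----------
    results
        One :class:`RankResult` per term in the universe.
    selected_terms
        The user's phenotype panel; must be a subset of the universe.
    top_fraction
        A gene is "top-ranked" in a term when its trust rank is at most
        ``top_fraction * n`` for that term's ranking.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    if not selected_terms:
        raise ValueError("selected_terms is empty")
    by_term = {r.term_id: r for r in results}
    universe = set(universe_terms) if universe_terms is not None else set(by_term)
    if not selected_terms <= universe:
        raise ValueError("selected_terms must be a subset of universe_terms")
    missing = universe - set(by_term)
    if missing:
        raise ValueError(f"no ranking for terms: {sorted(missing)}")
    background = universe - selected_terms

    genes = sorted({g for t in universe for g in by_term[t].table.index})
    top_by_term: dict[str, set[str]] = {}
    for t in universe:
        tab = by_term[t].table
        cutoff = top_fraction * len(tab)
        top_by_term[t] = set(tab.index[tab["trust_rank"] <= cutoff])

    absent_logged = False
    rows = []
    for g in genes:
        a = sum(g in top_by_term[t] for t in selected_terms)
        c = sum(g in top_by_term[t] for t in background)
        if not absent_logged and any(g not in by_term[t].table.index for t in universe):
            logger.info("some genes absent from some term rankings are "
                        "counted as not top-ranked")
            absent_logged = True
        b = len(selected_terms) - a
        d = len(background) - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((g, a, b, c, d, p))
    table = pd.DataFrame(rows, columns=["gene", "a", "b", "c", "d", "p"])
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["selected"] = table["q"] < fdr_threshold
    table = table.sort_values(["q", "p", "gene"]).reset_index(drop=True)
    return SelectionResult(
        table=table, fdr_threshold=fdr_threshold,
        selected=tuple(table.loc[table["selected"], "gene"]))
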