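"""Core ranking engine: TSPR, good seeds, TrustRank and spam mass.

The topic-sensitive PageRank (TSPR) score vector is the fixed point of

    x <- d * x . Pr + (1 - d) * pa

where Pr is the row-stochastic transition operator, pa the per-term
personalization vector, and d the damping factor (0.85 by default: the
probability of following an interaction edge rather than teleporting).
TrustRank solves the identical fixed point with the teleport vector gd
supported only on "good seeds" -- signature genes that also rank inside
the top-K TSPR scores -- which concentrates trust on genes reachable from
independently corroborated ones.  The spam mass of a gene,

    spammass = 1 - TrustRank / TSPR,

is negative when the good seeds elevate the gene (trustworthy) and
positive when its rank is driven by unrelated parts of the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from targo.network import GeneNetwork, TransitionOperator
from targo.signatures import SignatureSet, WeightVector, build_weight_vector

logger = logging.getLogger(__name__)


class NoGoodSeedsError(ValueError):
    """No signature gene ranked inside the seed candidate pool."""


@dataclass(frozen=True)
class RankingConfig:
    """Parameters of the propagation.

    d : damping factor in (0, 1), default 0.85.
    tol : L1 convergence tolerance of the power iteration.
    max_iter : iteration cap; hitting it logs a warning, not an error.
    seed_k : size of the top-TSPR candidate pool intersected with the
        signature to form good seeds (default 3000).
    spammass_cutoff : genes with spam mass above this are demoted when the
        spam-mass filter is on (default 0.0).
    min_support : strict lower bound on network-supported signature genes
        for a term to be ranked at all.
    """

    d: float = 0.85
    tol: float = 1e-10
    max_iter: int = 200
    seed_k: int = 3000
    spammass_cutoff: float = 0.0
    min_support: int = 10

    def __post_init__(self) -> None:
        # d = 0 (pure teleport) is allowed as a degenerate testing config
        if not 0.0 <= self.d < 1.0:
            raise ValueError(f"damping factor must be in [0, 1), got {self.d}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.seed_k < 1:
            raise ValueError("seed_k must be >= 1")


@dataclass(frozen=True)
class SeedVector:
    """Uniform teleport vector on the good seeds of one term."""

    term_id: str
    good_seeds: frozenset[str]
    gd: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class RankResult:
    """Per-gene scores and ranks for one term.

    ``table`` is indexed by gene and ordered by the final ranking (trust
    score descending, spam-mass-demoted genes last when the filter is on);
    columns: tspr_score, trust_score, spammass, tspr_rank, trust_rank,
    is_signature.  Spam mass is NaN where the TSPR score is zero
    (undefined, never silently 0).
    """

    term_id: str
    table: pd.DataFrame = field(repr=False)
    good_seeds: frozenset[str]
    tspr_iterations: int
    trust_iterations: int
    converged: bool


def _power_iteration(op: TransitionOperator, teleport: np.ndarray,
                     cfg: RankingConfig) -> tuple[np.ndarray, int, bool]:
    """Fixed point of x <- d*x.Pr + (1-d)*teleport, initialized at teleport.

    The fixed point is unique for 0 < d < 1, so initialization affects only
    the iteration count; starting at the teleport vector is reproducible.
    """
    x = teleport.copy()
    for it in range(1, cfg.max_iter + 1):
        x_new = cfg.d * op.propagate(x) + (1.0 - cfg.d) * teleport
        delta = float(np.abs(x_new - x).sum())
        x = x_new
        if delta < cfg.tol:
            x /= x.sum()
            return x, it, True
    logger.warning("power iteration did not converge in %d iterations "
                   "(last L1 change %.3e)", cfg.max_iter, delta)
    x /= x.sum()
    return x, cfg.max_iter, False


def run_tspr(op: TransitionOperator, pa: WeightVector,
             cfg: RankingConfig = RankingConfig()) -> tuple[np.ndarray, int, bool]:
    """Topic-sensitive PageRank scores for one term.

    Returns ``(scores, iterations, converged)``; scores are a probability
    distribution over network genes.
    """
    if not np.isclose(pa.pa.sum(), 1.0, atol=1e-9):
        raise ValueError("personalization vector must sum to 1")
    return _power_iteration(op, pa.pa, cfg)


def run_trustrank(op: TransitionOperator, gd: SeedVector,
                  cfg: RankingConfig = RankingConfig()) -> tuple[np.ndarray, int, bool]:
    """TrustRank scores: the same fixed point with the good-seed teleport."""
    if not gd.good_seeds:
        raise NoGoodSeedsError(f"term {gd.term_id}: empty seed vector")
    return _power_iteration(op, gd.gd, cfg)


def _ordinal_ranks(scores: np.ndarray) -> np.ndarray:
    """1-based ranks, score descending, ties broken by node index (gene id).

    Node order is lexicographic, so index order is identifier order.
    """
    order = np.lexsort((np.arange(scores.size), -scores))
    ranks = np.empty(scores.size, dtype=np.int64)
    ranks[order] = np.arange(1, scores.size + 1)
    return ranks


def select_good_seeds(tspr: np.ndarray, sig: SignatureSet, net: GeneNetwork,
                      cfg: RankingConfig = RankingConfig()) -> SeedVector:
    """Intersect the top ``seed_k`` TSPR genes with the term's signature.

    The seed vector gd is uniform 1/|good seeds| on the intersection.
    Boundary ties are broken by gene identifier so the pool has exactly
    ``seed_k`` members (or n, if smaller).
    """
    k = min(cfg.seed_k, net.n)
    order = np.lexsort((np.arange(net.n), -tspr))
    pool = set(order[:k])
    sig_idx = {net.node_index[g] for g in sig.genes if g in net.node_index}
    good = sorted(pool & sig_idx)
    if not good:
        raise NoGoodSeedsError(f"no good seeds for term {sig.term_id}")
    gd = np.zeros(net.n)
    gd[good] = 1.0 / len(good)
    return SeedVector(term_id=sig.term_id,
                      good_seeds=frozenset(net.nodes[i] for i in good), gd=gd)


def compute_spammass(tspr: np.ndarray, trust: np.ndarray) -> np.ndarray:
    """Elementwise 1 - trust/tspr; NaN (undefined) where tspr is 0."""
    if tspr.shape != trust.shape:
        raise ValueError("score vectors have mismatched lengths")
    out = np.full(tspr.shape, np.nan)
    nz = tspr > 0
    out[nz] = 1.0 - trust[nz] / tspr[nz]
    return out


def rank_term(net: GeneNetwork, op: TransitionOperator, sig: SignatureSet,
              cfg: RankingConfig = RankingConfig(),
              filter_spammass: bool = False) -> RankResult:
    """Full per-term pipeline: TSPR -> good seeds -> TrustRank -> spam mass.

    The output table is ordered by trust score descending (ties by gene
    identifier).  With ``filter_spammass`` on, genes whose spam mass
    exceeds ``cfg.spammass_cutoff`` are demoted below all retained genes;
    genes with undefined spam mass are never demoted.
    """
    pa = build_weight_vector(sig, net)
    tspr, it_tspr, conv1 = run_tspr(op, pa, cfg)
    seeds = select_good_seeds(tspr, sig, net, cfg)
    trust, it_trust, conv2 = run_trustrank(op, seeds, cfg)
    spammass = compute_spammass(tspr, trust)

    tspr_rank = _ordinal_ranks(tspr)
    trust_rank = _ordinal_ranks(trust)
    is_sig = np.array([g in sig.genes for g in net.nodes])

    table = pd.DataFrame({
        "tspr_score": tspr,
        "trust_score": trust,
        "spammass": spammass,
        "tspr_rank": tspr_rank,
        "trust_rank": trust_rank,
        "is_signature": is_sig,
    }, index=pd.Index(net.nodes, name="gene"))

    demoted = filter_spammass & (spammass > cfg.spammass_cutoff)
    # ordering keys: demoted last, then trust desc, then gene id asc
    order = np.lexsort((np.arange(net.n), -trust, demoted.astype(int)))
    table = table.iloc[order]
    return RankResult(term_id=sig.term_id, table=table,
                      good_seeds=seeds.good_seeds,
                      tspr_iterations=it_tspr, trust_iterations=it_trust,
                      converged=conv1 and conv2)


def rank_table_long(results: list[RankResult]) -> pd.DataFrame:
    """Concatenate per-term results into one long-format table for export."""
    frames = []
    for res in results:
        t = res.table.reset_index()
        t.insert(0, "term_id", res.term_id)
        t["converged"] = res.converged
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
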