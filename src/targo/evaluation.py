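"""Evaluation against known gene-term associations.

Two diagnostics are provided: ROC/AUC of a ranking against known
association labels, computed by default within the top-``top_n`` sublist
(the predicted candidates a reviewer would actually inspect), and the
hub-degree diagnostic -- the per-term Pearson correlation between
TrustRank score and node degree, which should stay low if the ranking is
driven by the signature rather than by hub connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from targo.network import GeneNetwork, TransitionOperator
from targo.ranking import NoGoodSeedsError, RankingConfig, RankResult, rank_term
from targo.signatures import SignatureSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RocReport:
    term_id: str
    auc: float | None          # None when a class is missing in the sublist
    n_pos: int
    n_neg: int
    points: pd.DataFrame = field(repr=False)  # fpr, tpr, threshold


@dataclass(frozen=True)
class DegreeDiagnostic:
    """Per-term degree-score Pearson r and the fraction below threshold."""

    per_term: pd.DataFrame = field(repr=False)  # term_id, r, defined
    threshold: float
    fraction_below: float


def evaluate_roc(scores: pd.Series, labels: pd.Series, top_n: int = 100,
                 scope: str = "top", term_id: str = "") -> RocReport:
    """ROC curve and AUC of a gene ranking against binary labels.

    Parameters
    ----------
    scores, labels
        Gene-indexed; labels in {0, 1}.  Genes missing a label are
        dropped.
    top_n
        Size of the sublist evaluated when ``scope == "top"``: the ROC is
        computed among the ``top_n`` highest-scoring labeled genes only.
        ``scope == "full"`` evaluates the whole labeled ranking instead.

    AUC is the trapezoid-rule area, equal to the Mann-Whitney probability
    that a random positive outscores a random negative with ties counted
    one half.  If the sublist lacks positives or negatives the AUC is
    undefined (None).
    """
    if scope not in ("top", "full"):
        raise ValueError(f"scope must be 'top' or 'full', got {scope!r}")
    common = scores.index.intersection(labels.index)
    s = scores.loc[common].astype(float)
    y = labels.loc[common].astype(int)
    if scope == "top":
        order = pd.DataFrame({"s": s, "g": common}).sort_values(
            ["s", "g"], ascending=[False, True]).index[:top_n]
        s, y = s.loc[order], y.loc[order]
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        logger.warning("term %s: AUC undefined (%d positives, %d negatives)",
                       term_id, n_pos, n_neg)
        return RocReport(term_id, None, n_pos, n_neg,
                         pd.DataFrame(columns=["fpr", "tpr", "threshold"]))
    fpr, tpr, thr = roc_curve(y.to_numpy(), s.to_numpy())
    return RocReport(term_id, float(_trapezoid_auc(fpr, tpr)), n_pos, n_neg,
                     pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}))


def degree_diagnostic(results: list[RankResult], net: GeneNetwork,
                      threshold: float = 0.6) -> DegreeDiagnostic:
    """Pearson r between TrustRank score and symmetrized node degree.

    Terms with zero variance in either quantity have undefined r and are
    excluded from the denominator of ``fraction_below``.
    """
    deg = pd.Series(net.total_degrees(), index=net.nodes, dtype=float)
    rows = []
    for res in results:
        trust = res.table["trust_score"]
        d = deg.loc[trust.index]
        if trust.std() == 0 or d.std() == 0:
            rows.append((res.term_id, np.nan, False))
            continue
        r, _ = pearsonr(trust.to_numpy(), d.to_numpy())
        rows.append((res.term_id, float(r), True))
    per_term = pd.DataFrame(rows, columns=["term_id", "r", "defined"])
    defined = per_term.loc[per_term["defined"], "r"]
    frac = float((defined < threshold).mean()) if len(defined) else float("nan")
    return DegreeDiagnostic(per_term=per_term, threshold=threshold,
                            fraction_below=frac)


def damping_sweep(net: GeneNetwork, op: TransitionOperator,
                  sigs: list[SignatureSet], labels: pd.DataFrame,
                  d_grid=(0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95),
                  top_n: int = 100, base_cfg: RankingConfig = RankingConfig(),
                  ) -> pd.DataFrame:
    """Mean TrustRank AUC across a grid of damping factors.

    ``labels`` is long-format with columns term_id, gene, label.  Terms
    without good seeds or with an undefined AUC at some d are skipped for
    that d.  Returns a tidy frame (d, mean_auc, n_terms).
    """
    rows = []
    for d in d_grid:
        cfg = RankingConfig(d=float(d), tol=base_cfg.tol,
                            max_iter=base_cfg.max_iter, seed_k=base_cfg.seed_k,
                            spammass_cutoff=base_cfg.spammass_cutoff,
                            min_support=base_cfg.min_support)
        aucs = []
        for sig in sigs:
            lab = labels.loc[labels["term_id"] == sig.term_id]
            if lab.empty:
                continue
            try:
                res = rank_term(net, op, sig, cfg)
            except NoGoodSeedsError:
                continue
            rep = evaluate_roc(res.table["trust_score"],
                               lab.set_index("gene")["label"],
                               top_n=top_n, term_id=sig.term_id)
            if rep.auc is not None:
                aucs.append(rep.auc)
        rows.append((float(d), float(np.mean(aucs)) if aucs else np.nan, len(aucs)))
    return pd.DataFrame(rows, columns=["d", "mean_auc", "n_terms"])
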