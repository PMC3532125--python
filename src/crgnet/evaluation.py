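"""Evaluation of predicted drug-gene pairs against the curated seed set.

Three instruments:

* hypergeometric over-representation -- are seed pairs concentrated among
  the predicted pairs, relative to all candidate pairs?
* ROC / AUC at the gene level -- does the fused centrality score rank seed
  genes above other genes better than |PCC| alone does?
* the matched-count baseline -- a correlation-only comparator constrained
  to predict exactly as many pairs as the combined method, swept over the
  same grid of centrality thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.metrics import roc_auc_score, roc_curve

from .correlation import seed_edge_mask
from .data_io import CompendiumEntry

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentEval",
    "hypergeom_overrep_p",
    "evaluate_overrep",
    "RocResult",
    "roc_auc",
    "baseline_predictions",
    "compare_with_baseline",
    "threshold_sweep",
]


@dataclass(frozen=True)
class EnrichmentEval:
    """Counts and p-value of seed-pair over-representation in predictions."""

    M: int        # all candidate pairs
    N_pred: int   # predicted pairs
    m: int        # seed pairs among candidates
    n_hit: int    # seed pairs among predictions
    p: float


def hypergeom_overrep_p(M: int, N_pred: int, m: int, n_hit: int) -> float:
    """Upper-tail hypergeometric p for >= n_hit seed pairs among N_pred
    predictions drawn from M candidates containing m seed pairs:
    p = sum_{x >= n_hit} C(N_pred, x) C(M - N_pred, m - x) / C(M, m).
    """
    if not (0 <= n_hit <= m <= M and n_hit <= N_pred <= M):
        raise ValueError(
            f"inconsistent counts M={M}, N_pred={N_pred}, m={m}, n_hit={n_hit}"
        )
    return float(hypergeom.sf(n_hit - 1, M, m, N_pred))


def evaluate_overrep(
    predictions: pd.DataFrame,
    edges: pd.DataFrame,
    seeds: Iterable[CompendiumEntry],
) -> EnrichmentEval:
    """Over-representation of seed pairs in a prediction table, with the
    full defined-edge table as the candidate universe."""
    seeds = list(seeds)
    m = int(seed_edge_mask(edges, seeds).sum())
    n_hit = int(seed_edge_mask(predictions, seeds).sum()) if len(predictions) else 0
    ev = EnrichmentEval(
        M=len(edges),
        N_pred=len(predictions),
        m=m,
        n_hit=n_hit,
        p=hypergeom_overrep_p(len(edges), len(predictions), m, n_hit),
    )
    logger.info(
        "over-representation: %d/%d seed pairs in %d predictions (p=%.3g)",
        ev.n_hit, ev.m, ev.N_pred, ev.p,
    )
    return ev


@dataclass(frozen=True)
class RocResult:
    auc: float
    n_pos: int
    n_neg: int
    sensitivity: tuple[float, ...]
    specificity: tuple[float, ...]


def roc_auc(scores: Mapping[str, float], labels: Mapping[str, bool]) -> RocResult:
    """ROC curve and AUC for item scores (higher = more likely positive).

    AUC equals the Mann-Whitney statistic U / (n_pos * n_neg) with tied
    scores contributing half credit.  Items present in ``labels`` but
    without a score are ignored.
    """
    items = [i for i in scores if i in labels]
    y = np.array([bool(labels[i]) for i in items])
    s = np.array([float(scores[i]) for i in items])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative item")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    return RocResult(
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
        sensitivity=tuple(tpr.tolist()),
        specificity=tuple((1.0 - fpr).tolist()),
    )


def baseline_predictions(edges: pd.DataFrame, k: int) -> pd.DataFrame:
    """Correlation-only comparator: the k edges with largest |PCC|.

    Deterministic tie-break at the k-th value by (|pcc| desc, drug, gene).
    """
    if k > len(edges):
        raise ValueError(f"k={k} exceeds the {len(edges)} available edges")
    if k == 0:
        return edges.iloc[0:0].copy()
    ordered = edges.assign(_abs=edges["pcc"].abs()).sort_values(
        ["_abs", "drug", "gene"], ascending=[False, True, True], kind="mergesort"
    )
    return ordered.head(k).drop(columns="_abs").reset_index(drop=True)


def compare_with_baseline(
    predictions: pd.DataFrame,
    edges: pd.DataFrame,
    seeds: Iterable[CompendiumEntry],
    combined_gene_scores: Mapping[str, float] | None = None,
    gene_labels: Mapping[str, bool] | None = None,
) -> dict:
    """One matched-count comparison of the combined method vs |PCC| alone.

    The baseline takes the top-K |PCC| edges with K = #predictions; both
    methods get seed-pair hit counts and over-representation p-values.  If
    gene-level scores/labels are supplied (combined scores are -q_score;
    baseline scores are the gene's max |PCC|), gene-level ROC AUCs are
    reported as well.
    """
    seeds = list(seeds)
    base = baseline_predictions(edges, len(predictions))
    report: dict = {
        "k": len(predictions),
        "combined": evaluate_overrep(predictions, edges, seeds),
        "baseline": evaluate_overrep(base, edges, seeds),
        "baseline_table": base,
    }
    if combined_gene_scores is not None:
        if gene_labels is None:
            seed_genes = {g for _, g in (e.key for e in seeds)}
            gene_labels = {g: g in seed_genes for g in combined_gene_scores}
        pcc_best = edges.assign(_abs=edges["pcc"].abs()).groupby("gene")["_abs"].max()
        baseline_scores = {
            g: float(pcc_best.get(g, 0.0)) for g in combined_gene_scores
        }
        report["combined_roc"] = roc_auc(combined_gene_scores, gene_labels)
        report["baseline_roc"] = roc_auc(baseline_scores, gene_labels)
    return report


def threshold_sweep(
    run_combined: Callable[[float, float], pd.DataFrame],
    edges: pd.DataFrame,
    seeds: Iterable[CompendiumEntry],
    thresholds: Sequence[float] = tuple(np.round(np.arange(0.01, 0.201, 0.01), 2)),
) -> pd.DataFrame:
    """Matched-count comparison across a grid of centrality top-fractions.

    ``run_combined(q_degree, q_betweenness)`` must return the combined
    method's prediction table at those thresholds; both fractions move
    together along ``thresholds``.  Returns one row per threshold with each
    method's seed-pair hit count and over-representation p.
    """
    seeds = list(seeds)
    rows = []
    for q in thresholds:
        preds = run_combined(q, q)
        rep = compare_with_baseline(preds, edges, seeds)
        rows.append(
            {
                "threshold": q,
                "n_predicted": rep["k"],
                "combined_hits": rep["combined"].n_hit,
                "combined_p": rep["combined"].p,
                "baseline_hits": rep["baseline"].n_hit,
                "baseline_p": rep["baseline"].p,
            }
        )
    return pd.DataFrame(rows)
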