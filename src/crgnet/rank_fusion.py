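"""Order-statistic rank fusion: combine ranks from several data sources.

Each data source ranks the genes; a gene's rank ratio in a source is
rank / n (rank 1 = best, so ratios live in (0, 1] and small is good).  The
Q statistic aggregates the ratios r_1..r_N of one gene across N sources as

    Q = N! * V_N,   V_0 = 1,
    V_k = sum_{i=1..k} (-1)^(i-1) * V_{k-i} * r_{N-k+1}^i / i!

with the ratios sorted ascending first.  Q is the probability that the
order statistics of N i.i.d. uniform(0,1) variables fall jointly below the
sorted ratios, i.e. P(U_(1) <= r_1, ..., U_(N) <= r_N); a small Q means the
gene ranks near the top in all sources simultaneously.  Here N = 2 (degree
and betweenness centrality), but the statistic is implemented for any N.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = ["rank_ratios", "q_statistic", "fuse_gene_ranks"]


def rank_ratios(
    scores: Mapping[str, float],
    higher_is_better: bool = True,
    tie_method: str = "average",
) -> dict[str, float]:
    """Rank ratio rank/n per gene, with rank 1 the best score.

    Ties receive the mean of their rank positions by default
    (``tie_method="average"``); ``"min"`` gives competition ranking.
    """
    if not scores:
        raise ValueError("no scores to rank")
    genes = list(scores)
    vals = [scores[g] for g in genes]
    ranks = rankdata([-v if higher_is_better else v for v in vals], method=tie_method)
    n = len(genes)
    return {g: float(r) / n for g, r in zip(genes, ranks)}


def q_statistic(ratios: Sequence[float]) -> float:
    """Joint tail probability of N rank ratios under the uniform-order-
    statistic null (see module docstring).  Input order is irrelevant;
    ratios are sorted ascending internally.  Each ratio must be in (0, 1].
    """
    r = sorted(float(x) for x in ratios)
    if not r:
        raise ValueError("need at least one rank ratio")
    if r[0] <= 0.0 or r[-1] > 1.0:
        raise ValueError("rank ratios must lie in (0, 1]")
    n = len(r)
    v = [0.0] * (n + 1)
    v[0] = 1.0
    for k in range(1, n + 1):
        base = r[n - k]  # r_{N-k+1} with 1-based indexing
        acc = 0.0
        power = 1.0
        for i in range(1, k + 1):
            power *= base
            acc += (-1.0) ** (i - 1) * v[k - i] * power / math.factorial(i)
        v[k] = acc
    q = math.factorial(n) * v[n]
    # the recursion is exact in exact arithmetic; clamp float residue only
    return float(min(max(q, 0.0), 1.0))


def fuse_gene_ranks(
    profile: pd.DataFrame,
    genes: Iterable[str] | None = None,
    tie_method: str = "average",
) -> pd.DataFrame:
    """Fuse degree and betweenness ranks into one Q score per gene.

    Ranks are computed among ``genes`` (default: every profiled gene), both
    metrics higher-is-better.  Returns a DataFrame with columns gene,
    rank_ratio_degree, rank_ratio_betweenness, q_score, sorted ascending by
    (q_score, gene) -- smaller q means jointly stronger centrality.  Genes
    missing from the profile are excluded with a warning.
    """
    if genes is None:
        present = list(profile.index)
    else:
        genes = list(dict.fromkeys(genes))
        present = [g for g in genes if g in profile.index]
        if len(present) < len(genes):
            logger.warning(
                "%d genes lack centrality values and are excluded from fusion",
                len(genes) - len(present),
            )
    if not present:
        raise ValueError("no gene has a centrality profile")
    deg = rank_ratios(profile.loc[present, "degree"].to_dict(), tie_method=tie_method)
    btw = rank_ratios(
        profile.loc[present, "betweenness"].to_dict(), tie_method=tie_method
    )
    out = pd.DataFrame(
        {
            "gene": present,
            "rank_ratio_degree": [deg[g] for g in present],
            "rank_ratio_betweenness": [btw[g] for g in present],
        }
    )
    out["q_score"] = [
        q_statistic((d, b))
        for d, b in zip(out["rank_ratio_degree"], out["rank_ratio_betweenness"])
    ]
    return out.sort_values(["q_score", "gene"], kind="mergesort", ignore_index=True)
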