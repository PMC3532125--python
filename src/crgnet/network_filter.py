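"""Protein-interaction-network filter: centrality profiles and null models.

Two node statistics drive this filter: degree (neighbor count; hubs
maintain network connectivity) and betweenness centrality (for node i,
B_i = sum over unordered node pairs {s,t}, s != i != t, of the fraction of
shortest s-t paths passing through i; bottlenecks control information
flow).  Betweenness is unnormalized and counts each pair once; pairs in
different components contribute zero.  Downstream steps consume only the
rankings, which every standard convention shares.

Seed genes are compared to size-matched random gene sets drawn from the
network (empirical permutation null with the +1 correction), and the filter
itself retains genes in the top fraction of both centrality distributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "degree_map",
    "betweenness_map",
    "centrality_profile",
    "NullComparison",
    "random_set_null_comparison",
    "top_fraction_filter",
]


def degree_map(network: nx.Graph) -> dict[str, int]:
    """Neighbor count per gene."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    return dict(network.degree())


def betweenness_map(network: nx.Graph) -> dict[str, float]:
    """Unnormalized betweenness centrality per gene (unordered pairs,
    endpoints excluded).  Computed with igraph's exact Brandes algorithm."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = list(network.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    g = ig.Graph(
        n=len(nodes),
        edges=[(index[a], index[b]) for a, b in network.edges()],
        directed=False,
    )
    vals = g.betweenness(directed=False)
    return {n: float(v) for n, v in zip(nodes, vals)}


def centrality_profile(network: nx.Graph) -> pd.DataFrame:
    """Per-gene DataFrame with columns ``degree`` and ``betweenness``."""
    deg = degree_map(network)
    btw = betweenness_map(network)
    return pd.DataFrame(
        {"degree": pd.Series(deg, dtype=float), "betweenness": pd.Series(btw)}
    ).sort_index()


@dataclass(frozen=True)
class NullComparison:
    """Seed-set centrality against size-matched random gene sets."""

    metric: str
    observed_mean: float
    null_mean: float
    fold: float
    p_empirical: float
    n_perm: int
    n_seed: int
    seed: int


def random_set_null_comparison(
    profile: pd.DataFrame,
    seed_genes: Iterable[str],
    metric: str = "degree",
    n_perm: int = 999,
    seed: int = 0,
) -> NullComparison:
    """Compare the seed genes' mean centrality to random same-size sets.

    Random sets are sampled without replacement from all network genes;
    the one-sided empirical p for observed >= null uses the +1 correction:
    p = (#{null mean >= observed mean} + 1) / (n_perm + 1).
    """
    if metric not in profile.columns:
        raise ValueError(f"unknown metric {metric!r}")
    in_net = [g for g in dict.fromkeys(seed_genes) if g in profile.index]
    if len(in_net) < 2:
        raise ValueError("need >= 2 seed genes present in the network")
    values = profile[metric].to_numpy(dtype=float)
    observed = float(profile.loc[in_net, metric].mean())
    rng = np.random.default_rng(seed)
    k, n = len(in_net), len(values)
    null_means = np.empty(n_perm)
    for i in range(n_perm):
        null_means[i] = values[rng.choice(n, size=k, replace=False)].mean()
    null_mean = float(null_means.mean())
    p = (int((null_means >= observed).sum()) + 1) / (n_perm + 1)
    fold = observed / null_mean if null_mean != 0 else math.inf
    logger.info(
        "%s null: observed %.4g vs null %.4g (fold %.3g, p=%.4g)",
        metric, observed, null_mean, fold, p,
    )
    return NullComparison(
        metric=metric,
        observed_mean=observed,
        null_mean=null_mean,
        fold=fold,
        p_empirical=p,
        n_perm=n_perm,
        n_seed=k,
        seed=seed,
    )


def _upper_quantile_threshold(values: np.ndarray, q: float) -> float:
    """Nearest-rank value separating the top fraction q of *values*.

    With n values sorted ascending, the threshold is the element at rank
    ceil((1-q) * n); q = 1 admits everything.
    """
    n = len(values)
    rank = math.ceil((1.0 - q) * n)
    if rank < 1:
        return -math.inf
    return float(np.sort(values)[rank - 1])


def top_fraction_filter(
    profile: pd.DataFrame,
    genes: Iterable[str],
    q_degree: float = 0.01,
    q_betweenness: float = 0.01,
) -> frozenset[str]:
    """Genes in the top ``q_degree`` fraction of network-wide degree AND the
    top ``q_betweenness`` fraction of betweenness.

    Thresholds are nearest-rank quantiles of the full network distributions;
    ties at the cut are admitted (weak inequality), so the filter is
    monotone in both fractions.  Genes absent from the network never pass.
    """
    for name, q in (("q_degree", q_degree), ("q_betweenness", q_betweenness)):
        if not 0 < q <= 1:
            raise ValueError(f"{name} must be in (0, 1]")
    thr_deg = _upper_quantile_threshold(profile["degree"].to_numpy(float), q_degree)
    thr_btw = _upper_quantile_threshold(
        profile["betweenness"].to_numpy(float), q_betweenness
    )
    out = set()
    for g in genes:
        if g not in profile.index:
            continue
        if profile.at[g, "degree"] >= thr_deg and profile.at[g, "betweenness"] >= thr_btw:
            out.add(g)
    logger.info(
        "centrality filter (q_deg=%g, q_btw=%g): %d genes pass", q_degree, q_betweenness, len(out)
    )
    return frozenset(out)
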