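"""Independent brute-force oracles used to verify the implementations.

Each oracle recomputes a quantity by a route the package itself does not
use: exhaustive enumeration, exact rational arithmetic, or Monte-Carlo
simulation.  They are intentionally slow and only run on tiny inputs.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np


def mc_order_statistic_q(ratios, n_draws=100_000, rng=None) -> tuple[float, float]:
    """Monte-Carlo estimate (and its SE) of P(U_(j) <= r_j for all j) for
    sorted ratios r, with U_(j) the order statistics of iid uniforms."""
    rng = rng or np.random.default_rng(0)
    r = np.sort(np.asarray(ratios, dtype=float))
    u = np.sort(rng.random((n_draws, len(r))), axis=1)
    hit = (u <= r).all(axis=1)
    p = hit.mean()
    se = math.sqrt(max(p * (1 - p), 1e-12) / n_draws)
    return float(p), float(se)


def brute_force_betweenness(graph: nx.Graph) -> dict:
    """Unordered-pair, endpoint-excluded betweenness by enumerating every
    shortest path between every node pair."""
    acc = {n: 0.0 for n in graph}
    nodes = list(graph)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        d_st = len(paths)
        for node in nodes:
            if node in (s, t):
                continue
            delta = sum(node in p for p in paths)
            if delta:
                acc[node] += delta / d_st
    return acc


def exact_fisher_tail(a: int, b: int, c: int, d: int) -> Fraction:
    """Upper-tail Fisher p by enumerating all tables with the observed
    margins, in exact rational arithmetic."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def point(a_: int) -> Fraction:
        b_, c_ = row1 - a_, col1 - a_
        d_ = row2 - c_
        if min(b_, c_, d_) < 0:
            return Fraction(0)
        return Fraction(
            math.factorial(row1) * math.factorial(row2)
            * math.factorial(col1) * math.factorial(n - col1),
            math.factorial(n) * math.factorial(a_) * math.factorial(b_)
            * math.factorial(c_) * math.factorial(d_),
        )

    return sum((point(a_) for a_ in range(a, min(row1, col1) + 1)), Fraction(0))


def exact_fisher_point(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact point probability of one 2x2 table at fixed margins."""
    return exact_fisher_tail(a, b, c, d) - exact_fisher_tail(a + 1, b - 1, c - 1, d + 1)


def exhaustive_overrep_p(M: int, N_pred: int, m: int, n_hit: int) -> Fraction:
    """Fraction of all C(M, N_pred) prediction sets containing >= n_hit of
    the m seed items, by direct enumeration.  Only feasible for M <= 12."""
    items = range(M)
    seeds = set(range(m))
    total = hits = 0
    for subset in itertools.combinations(items, N_pred):
        total += 1
        if len(seeds.intersection(subset)) >= n_hit:
            hits += 1
    return Fraction(hits, total)


def pairwise_auc(pos, neg) -> float:
    """AUC by counting won/tied score pairs."""
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))
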