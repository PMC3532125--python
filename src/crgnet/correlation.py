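"""Drug-activity / gene-expression correlation: the expression-based filter.

The initial drug-candidate gene network is bipartite: drug nodes with
activity profiles (lgGI50 across the cell-line panel) and gene nodes with
expression profiles.  Each (drug, gene) edge is weighted by the Pearson
correlation coefficient computed over the cell lines where the drug's
activity is observed (activity matrices are gappy; expression is complete).

The expression filter keeps edges whose |PCC| clears a data-driven
threshold: the p-th percentile (default 5) of the ascending-sorted |PCC| of
the curated seed pairs, so that (100-p)% of documented drug-gene
relationships would survive their own cut.  Seed-pair correlations can also
be classified against a per-drug correlation null with the z statistic
z = |pcc - mu| / delta, where mu and delta summarize the drug's PCCs over
all genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_io import CompendiumEntry, normalize_drug, normalize_gene

logger = logging.getLogger(__name__)

__all__ = [
    "filter_drugs_by_missingness",
    "pairwise_pcc",
    "build_edge_table",
    "seed_edge_mask",
    "ccrg_abs_pcc_threshold",
    "PairNullResult",
    "drug_null_z",
    "classify_seed_pairs",
    "pcc_distribution_summary",
]

EDGE_COLUMNS = ["drug", "gene", "pcc", "n_complete"]


def filter_drugs_by_missingness(
    activity: pd.DataFrame, max_missing_fraction: float = 0.8
) -> pd.DataFrame:
    """Drop drugs whose activity is missing in more than the given fraction
    of cell lines (strictly greater; a drug at exactly the threshold stays).
    """
    if not 0 < max_missing_fraction < 1:
        raise ValueError("max_missing_fraction must be in (0, 1)")
    frac = activity.isna().mean(axis=1)
    removed = activity.index[frac > max_missing_fraction]
    if len(removed):
        logger.info(
            "missingness filter removed %d/%d drugs: %s",
            len(removed), len(activity), list(removed[:10]),
        )
    kept = activity.drop(index=removed)
    if kept.empty:
        raise ValueError("all drugs removed by the missingness filter")
    return kept


def pairwise_pcc(
    x: Sequence[float], y: Sequence[float], min_complete: int = 10
) -> tuple[float, int]:
    """Pearson correlation over jointly observed positions of two series.

    Returns ``(pcc, n_complete)``; ``pcc`` is NaN (undefined) when fewer
    than ``min_complete`` complete pairs remain or either sub-series is
    constant.  ``min_complete`` must be at least 3.
    """
    if min_complete < 3:
        raise ValueError("min_complete must be >= 3")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < min_complete:
        return (math.nan, n)
    xs, ys = x[mask], y[mask]
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    denom = math.sqrt((xs @ xs) * (ys @ ys))
    if denom == 0.0:
        return (math.nan, n)
    return (float(np.clip((xs @ ys) / denom, -1.0, 1.0)), n)


def build_edge_table(
    activity: pd.DataFrame,
    expression: pd.DataFrame,
    min_complete: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate every drug against every gene over shared cell lines.

    Returns ``(edges, undefined)``: *edges* has one row per (drug, gene)
    with a defined PCC (columns drug, gene, pcc, n_complete); *undefined*
    records the pairs whose correlation could not be computed and why
    (too few complete cells, or a zero-variance drug/gene sub-series).

    Vectorized per drug: with expression complete, the observation mask --
    and hence n_complete -- depends only on the drug.
    """
    shared = [c for c in expression.columns if c in set(activity.columns)]
    if len(shared) < min_complete:
        raise ValueError(
            f"only {len(shared)} shared cell lines; need >= min_complete={min_complete}"
        )
    expr = expression[shared].to_numpy()
    genes = expression.index.to_numpy()
    rows: list[pd.DataFrame] = []
    undef: list[tuple[str, str, int, str]] = []
    for drug, act_row in activity[shared].iterrows():
        a = act_row.to_numpy(dtype=float)
        mask = np.isfinite(a)
        n = int(mask.sum())
        if n < min_complete:
            undef.extend((drug, g, n, "insufficient_cells") for g in genes)
            continue
        av = a[mask] - a[mask].mean()
        norm_a = math.sqrt(av @ av)
        if norm_a == 0.0:
            undef.extend((drug, g, n, "zero_variance_drug") for g in genes)
            continue
        sub = expr[:, mask]
        sub = sub - sub.mean(axis=1, keepdims=True)
        norms = np.sqrt((sub * sub).sum(axis=1))
        ok = norms > 0
        pcc = np.full(len(genes), np.nan)
        pcc[ok] = np.clip((sub[ok] @ av) / (norms[ok] * norm_a), -1.0, 1.0)
        undef.extend((drug, g, n, "zero_variance_gene") for g in genes[~ok])
        rows.append(
            pd.DataFrame(
                {"drug": drug, "gene": genes[ok], "pcc": pcc[ok], "n_complete": n}
            )
        )
    edges = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=EDGE_COLUMNS)
    )
    undefined = pd.DataFrame(undef, columns=["drug", "gene", "n_complete", "reason"])
    if edges.empty:
        raise ValueError("no (drug, gene) pair has a defined correlation")
    logger.info(
        "edge table: %d defined edges, %d undefined pairs", len(edges), len(undefined)
    )
    return edges, undefined


def seed_edge_mask(
    edges: pd.DataFrame, seeds: Iterable[CompendiumEntry]
) -> pd.Series:
    """Boolean mask over edge rows marking curated (drug, gene) seed pairs."""
    keys = {e.key for e in seeds}
    drugs = edges["drug"].map(normalize_drug)
    genes = edges["gene"].map(normalize_gene)
    return pd.Series(
        [(d, g) in keys for d, g in zip(drugs, genes)], index=edges.index
    )


def ccrg_abs_pcc_threshold(
    edges: pd.DataFrame,
    seeds: Iterable[CompendiumEntry],
    percentile: float = 5.0,
) -> float:
    """|PCC| threshold = nearest-rank percentile of the seed pairs' |PCC|.

    The absolute correlations of seed pairs with a defined PCC are sorted
    ascending and the value at rank ``ceil(percentile/100 * N)`` is the
    threshold, so at least (100-percentile)% of seed pairs pass it.  A
    non-positive percentile disables the cut (threshold 0).
    """
    if percentile > 100:
        raise ValueError("percentile must be <= 100")
    if percentile <= 0:
        return 0.0
    mask = seed_edge_mask(edges, seeds)
    vals = np.sort(np.abs(edges.loc[mask, "pcc"].to_numpy()))
    if len(vals) == 0:
        raise ValueError("no seed pair has a defined correlation")
    rank = math.ceil(percentile / 100.0 * len(vals))
    return float(vals[max(rank, 1) - 1])


@dataclass(frozen=True)
class PairNullResult:
    """A seed pair's correlation against its drug's correlation null."""

    drug_id: str
    gene_id: str
    pcc: float
    mu: float
    delta: float
    z: float
    label: str  # "larger" | "smaller" | "random"


def drug_null_z(
    drug_id: str,
    gene_id: str,
    pcc: float,
    drug_pccs: Sequence[float],
    z_threshold: float = 0.8,
    ddof: int = 0,
    min_pccs: int = 30,
) -> PairNullResult:
    """Classify one pair's PCC against the drug's all-gene PCC distribution.

    z = |pcc - mu| / delta with mu, delta the mean and standard deviation
    (population, ddof=0, by default) of the drug's PCCs over all genes.
    ``z < z_threshold`` labels the pair "random"; otherwise the sign of
    (pcc - mu) decides "larger" vs "smaller".
    """
    vals = np.asarray(drug_pccs, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < min_pccs:
        raise ValueError(f"need >= {min_pccs} defined PCCs for the drug null")
    mu = float(vals.mean())
    delta = float(vals.std(ddof=ddof))
    if delta == 0.0:
        raise ValueError("degenerate drug null: zero standard deviation")
    z = abs(pcc - mu) / delta
    if z < z_threshold:
        label = "random"
    else:
        label = "larger" if pcc > mu else "smaller"
    return PairNullResult(drug_id, gene_id, pcc, mu, delta, z, label)


def classify_seed_pairs(
    edges: pd.DataFrame,
    seeds: Iterable[CompendiumEntry],
    z_threshold: float = 0.8,
    ddof: int = 0,
    min_pccs: int = 30,
) -> list[PairNullResult]:
    """Apply :func:`drug_null_z` to every seed pair present in the edge table."""
    mask = seed_edge_mask(edges, seeds)
    by_drug = {d: g["pcc"].to_numpy() for d, g in edges.groupby("drug")}
    results = []
    for _, row in edges.loc[mask].iterrows():
        results.append(
            drug_null_z(
                row["drug"], row["gene"], row["pcc"], by_drug[row["drug"]],
                z_threshold=z_threshold, ddof=ddof, min_pccs=min_pccs,
            )
        )
    return results


def pcc_distribution_summary(
    pccs: Sequence[float], bands: Sequence[float] = (0.3, 0.5), n_bins: int = 20
) -> dict:
    """Fractions of correlations within symmetric |pcc| bands plus a histogram.

    Mirrors the weak-correlation summary of seed pairs (e.g. the share of
    pairs with PCC in [-0.3, 0.3]).  Empty input yields an empty summary
    with a warning.
    """
    vals = np.asarray(list(pccs), dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        logger.warning("no defined correlations to summarize")
        return {"n": 0, "bands": {}, "hist_counts": [], "hist_edges": []}
    counts, edges_ = np.histogram(vals, bins=n_bins, range=(-1.0, 1.0))
    return {
        "n": int(len(vals)),
        "bands": {b: float((np.abs(vals) <= b).mean()) for b in bands},
        "hist_counts": counts.tolist(),
        "hist_edges": edges_.tolist(),
    }
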