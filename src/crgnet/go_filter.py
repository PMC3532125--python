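"""Annotation-based candidate filter: depth-limited Fisher-exact enrichment.

The seed genes are tested for over-representation in every annotation term
with a one-sided Fisher exact test on the standard 2x2 table

    a = seed genes in the term          b = other background genes in term
    c = seed genes not in the term      d = other background genes not in term

restricted to terms at a fixed ontology depth (shortest path from the
namespace root; default depth 5, mirroring DAVID's level files).  Terms
with tail p <= alpha (default 0.01, no multiple-testing correction by
default) are "enriched", and the union of their annotated genes is the
candidate set the rest of the pipeline prunes.

Both the exact point probability of the observed table (the printed
factorial formula) and the upper-tail enrichment p are exposed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .data_io import AnnotationSet, OntologyGraph, normalize_gene

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "term_depths",
    "term_depth",
    "fisher_point_probability",
    "fisher_enrichment_p",
    "enriched_terms",
    "candidate_genes_from_terms",
    "TermSimilarityResult",
    "term_set_similarity",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Disjoint 2x2 counts for one study-set vs one annotation term."""

    a: int  # study genes annotated to the term
    b: int  # background-minus-study genes annotated to the term
    c: int  # study genes not annotated
    d: int  # background-minus-study genes not annotated

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    table: ContingencyTable
    p_point: float
    p_tail: float
    depth: int
    namespace: str | None = None
    name: str | None = None


# ---------------------------------------------------------------------------
# ontology depth
# ---------------------------------------------------------------------------


def term_depths(ontology: OntologyGraph) -> dict[str, int]:
    """Depth of every term: shortest child->parent path length to a root.

    Multi-source BFS from the roots along reversed (parent->child) edges;
    with one root per namespace this is the depth within the term's own
    namespace, since a term only descends from its namespace root.
    """
    rev = ontology.graph.reverse(copy=False)
    depths: dict[str, int] = {r: 0 for r in ontology.roots}
    frontier = list(ontology.roots)
    d = 0
    while frontier:
        d += 1
        nxt = []
        for node in frontier:
            for child in rev.successors(node):
                if child not in depths:
                    depths[child] = d
                    nxt.append(child)
        frontier = nxt
    return depths


def term_depth(ontology: OntologyGraph, term_id: str) -> int:
    if term_id not in ontology:
        raise KeyError(f"unknown ontology term {term_id!r}")
    return term_depths(ontology)[term_id]


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------


def _check_margins(t: ContingencyTable) -> None:
    if (t.a + t.b) <= 0 or (t.c + t.d) <= 0 or (t.a + t.c) <= 0 or (t.b + t.d) <= 0:
        raise ValueError("all four margins of the 2x2 table must be positive")


def fisher_point_probability(t: ContingencyTable) -> float:
    """Exact hypergeometric probability of the observed 2x2 table.

    (a+b)! (c+d)! (a+c)! (b+d)! / (n! a! b! c! d!), evaluated in log space.
    """
    _check_margins(t)
    return float(hypergeom.pmf(t.a, t.n, t.a + t.b, t.a + t.c))


def fisher_enrichment_p(t: ContingencyTable) -> float:
    """One-sided enrichment p: sum of point probabilities over tables with
    a' >= a at the observed margins (upper hypergeometric tail)."""
    _check_margins(t)
    return float(hypergeom.sf(t.a - 1, t.n, t.a + t.b, t.a + t.c))


def _depth_ok(depth: int, depth_limit: int, depth_rule: str) -> bool:
    if depth_rule == "eq":
        return depth == depth_limit
    if depth_rule == "le":
        return depth <= depth_limit
    if depth_rule == "any":
        return True
    raise ValueError(f"unknown depth_rule {depth_rule!r}")


def enriched_terms(
    study_genes,
    annotation: AnnotationSet,
    ontology: OntologyGraph,
    background=None,
    alpha: float = 0.01,
    depth_limit: int = 5,
    depth_rule: str = "eq",
    correction: str | None = None,
) -> list[EnrichmentResult]:
    """Terms in which the study genes are over-represented.

    Background defaults to all annotated genes; the study set is restricted
    to it.  Terms failing the depth rule ("eq": depth == depth_limit, "le":
    depth <= depth_limit, "any") are not tested.  ``correction="fdr_bh"``
    optionally applies Benjamini-Hochberg to the tail p-values before the
    alpha cut; the default is the raw per-term threshold.
    """
    if background is None:
        background = annotation.annotated_genes()
    background = frozenset(normalize_gene(g) for g in background)
    study = frozenset(normalize_gene(g) for g in study_genes) & background
    annotated_study = study & annotation.annotated_genes()
    if not annotated_study:
        raise ValueError("no study gene is annotated within the background")
    depths = term_depths(ontology)
    rest = background - study
    tested: list[EnrichmentResult] = []
    for term, genes in annotation.term_genes.items():
        depth = depths.get(term)
        if depth is None or not _depth_ok(depth, depth_limit, depth_rule):
            continue
        in_term = genes & background
        if not in_term:
            continue
        a = len(genes & study)
        b = len(genes & rest)
        table = ContingencyTable(a=a, b=b, c=len(study) - a, d=len(rest) - b)
        try:
            _check_margins(table)
        except ValueError:
            continue
        tested.append(
            EnrichmentResult(
                term_id=term,
                table=table,
                p_point=fisher_point_probability(table),
                p_tail=fisher_enrichment_p(table),
                depth=depth,
                namespace=annotation.term_namespaces.get(term),
                name=annotation.term_names.get(term),
            )
        )
    if correction == "fdr_bh":
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(
            [r.p_tail for r in tested], alpha=alpha, method="fdr_bh"
        )
        out = [r for r, keep in zip(tested, reject) if keep]
    elif correction is None:
        out = [r for r in tested if r.p_tail <= alpha]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    out.sort(key=lambda r: (r.p_tail, r.term_id))
    logger.info("%d/%d depth-eligible terms enriched at alpha=%g", len(out), len(tested), alpha)
    return out


def candidate_genes_from_terms(
    results: list[EnrichmentResult],
    annotation: AnnotationSet,
    measured=None,
) -> frozenset[str]:
    """Union of genes annotated to the enriched terms (the candidate set),
    optionally restricted to measured genes."""
    out: set[str] = set()
    for r in results:
        out |= annotation.term_genes.get(r.term_id, frozenset())
    if measured is not None:
        out &= frozenset(normalize_gene(g) for g in measured)
    if not out:
        logger.warning("no candidate genes: enriched-term union is empty")
    return frozenset(out)


# ---------------------------------------------------------------------------
# term-set similarity characterization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TermSimilarityResult:
    observed: float | None
    null_means: tuple[float | None, ...]
    p_empirical: float | None
    n_terms: int


def _mean_pairwise_jaccard(terms: list[str], annotation: AnnotationSet) -> float | None:
    if len(terms) < 2:
        return None
    sims = []
    for t1, t2 in itertools.combinations(terms, 2):
        g1, g2 = annotation.term_genes[t1], annotation.term_genes[t2]
        union = len(g1 | g2)
        sims.append(len(g1 & g2) / union if union else 0.0)
    return float(np.mean(sims))


def term_set_similarity(
    study_genes,
    annotation: AnnotationSet,
    ontology: OntologyGraph,
    background=None,
    n_draws: int = 100,
    seed: int | np.random.Generator = 0,
    **enrich_kwargs,
) -> TermSimilarityResult:
    """Functional coherence of the study set's enriched terms vs random sets.

    Similarity between two terms is the Jaccard index of their annotated
    gene sets; the score of a term list is its mean over all pairs.  The
    null redraws gene sets of the same size from the background ``n_draws``
    times and re-runs the enrichment; p_empirical = (#{null >= observed}+1)
    / (n_draws+1).  Draws (or the study) with fewer than two enriched terms
    have undefined similarity; undefined nulls count as non-exceeding.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if background is None:
        background = annotation.annotated_genes()
    background = sorted(frozenset(normalize_gene(g) for g in background))
    study = frozenset(normalize_gene(g) for g in study_genes) & frozenset(background)
    try:
        results = enriched_terms(study, annotation, ontology, background, **enrich_kwargs)
    except ValueError:
        results = []
    observed = _mean_pairwise_jaccard([r.term_id for r in results], annotation)
    null_means: list[float | None] = []
    for _ in range(n_draws):
        draw = rng.choice(len(background), size=len(study), replace=False)
        draw_genes = frozenset(background[i] for i in draw)
        try:
            null_res = enriched_terms(
                draw_genes, annotation, ontology, background, **enrich_kwargs
            )
        except ValueError:
            null_means.append(None)
            continue
        null_means.append(
            _mean_pairwise_jaccard([r.term_id for r in null_res], annotation)
        )
    if observed is None:
        logger.warning("fewer than 2 enriched study terms; similarity undefined")
        p = None
    else:
        exceed = sum(1 for m in null_means if m is not None and m >= observed)
        p = (exceed + 1) / (n_draws + 1)
    return TermSimilarityResult(
        observed=observed,
        null_means=tuple(null_means),
        p_empirical=p,
        n_terms=len(results),
    )
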