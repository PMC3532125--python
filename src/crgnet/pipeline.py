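"""End-to-end prioritization: three filters, then rank fusion.

Stage order (each stage logs its in/out cardinalities):

1. drop drugs with too much missing activity;
2. build the drug x gene correlation edge table over shared cell lines;
3. annotation filter -- enrich the seed genes' terms, keep genes annotated
   to enriched terms (a gene-level cut);
4. network filter -- keep genes in the top fraction of both degree and
   betweenness in the interaction network (gene-level);
5. expression filter -- keep edges with |PCC| at or above the seed-derived
   percentile threshold (edge-level);
6. rank fusion -- Q statistic over degree/betweenness ranks of the
   surviving genes, attached to every surviving edge.

Genes absent from the network or from the annotation fail the respective
filter.  A stage that empties the candidate set raises a
:class:`PipelineStageError` naming the stage and its threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from . import __version__
from .correlation import (
    build_edge_table,
    ccrg_abs_pcc_threshold,
    classify_seed_pairs,
    filter_drugs_by_missingness,
    pcc_distribution_summary,
    seed_edge_mask,
)
from .data_io import (
    AnnotationSet,
    CompendiumEntry,
    OntologyGraph,
    PREDICTION_COLUMNS,
    align_cell_lines,
    normalize_gene,
)
from .evaluation import baseline_predictions
from .go_filter import candidate_genes_from_terms, enriched_terms
from .network_filter import (
    centrality_profile,
    random_set_null_comparison,
    top_fraction_filter,
)
from .rank_fusion import fuse_gene_ranks

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "PipelineStageError", "run_pipeline", "run_baseline"]


class PipelineStageError(RuntimeError):
    """A pipeline stage left no candidates; names the stage and threshold."""


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and knobs of the full prioritization run.

    Defaults: enrichment alpha 0.01 at ontology depth exactly 5; top 1% of
    both centrality distributions; |PCC| threshold at the 5th percentile of
    seed-pair |PCC|; drugs dropped above 80% missing activity; z threshold
    0.8 for the per-drug correlation null.
    """

    alpha: float = 0.01
    depth_limit: int = 5
    depth_rule: str = "eq"
    q_degree: float = 0.01
    q_betweenness: float = 0.01
    pcc_percentile: float = 5.0
    min_complete: int = 10
    max_missing_fraction: float = 0.8
    z_threshold: float = 0.8
    n_perm: int = 999
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        for name in ("q_degree", "q_betweenness"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 <= self.pcc_percentile <= 100:
            raise ValueError("pcc_percentile must be in [0, 100]")

    def manifest(self) -> dict:
        """Provenance record serialized into run outputs."""
        return {"software": f"crgnet {__version__}", **asdict(self)}


@dataclass
class PipelineResult:
    predictions: pd.DataFrame
    edges: pd.DataFrame
    undefined_edges: pd.DataFrame
    tau: float
    enrichment: list
    candidate_genes: frozenset[str]
    network_pass_genes: frozenset[str]
    fusion: pd.DataFrame
    null_comparisons: dict
    seed_pcc_summary: dict
    seed_classification: list
    config: PipelineConfig

    def manifest(self) -> dict:
        return {
            **self.config.manifest(),
            "n_edges": len(self.edges),
            "n_predictions": len(self.predictions),
            "tau": self.tau,
        }


def _stage(name: str, survivors: int, threshold: str) -> None:
    if survivors == 0:
        raise PipelineStageError(
            f"stage {name!r} left no candidates (threshold {threshold})"
        )


def run_pipeline(
    expression: pd.DataFrame,
    activity: pd.DataFrame,
    network: nx.Graph,
    annotation: AnnotationSet,
    ontology: OntologyGraph,
    compendium: Iterable[CompendiumEntry],
    config: PipelineConfig = PipelineConfig(),
    characterize: bool = True,
) -> PipelineResult:
    """Run the combined filter pipeline on loaded inputs.

    ``characterize=False`` skips the permutation null comparisons and
    seed-pair classification reports (the prediction table is unaffected).
    """
    compendium = list(compendium)
    seed_genes = sorted({normalize_gene(e.gene_symbol) for e in compendium})
    measured = frozenset(expression.index)

    # stage 1-2: missingness filter, correlation edge table
    expression, activity = align_cell_lines(expression, activity)
    activity = filter_drugs_by_missingness(activity, config.max_missing_fraction)
    edges, undefined = build_edge_table(activity, expression, config.min_complete)
    logger.info("stage edges: %d drugs x %d genes -> %d defined edges",
                activity.shape[0], expression.shape[0], len(edges))

    # stage 3: annotation filter (gene level)
    seed_in_ann = [g for g in seed_genes if g in annotation.annotated_genes()]
    background = annotation.annotated_genes() & measured
    enrichment = enriched_terms(
        seed_in_ann,
        annotation,
        ontology,
        background=background,
        alpha=config.alpha,
        depth_limit=config.depth_limit,
        depth_rule=config.depth_rule,
    )
    candidates = candidate_genes_from_terms(enrichment, annotation, measured=measured)
    _stage("annotation_filter", len(candidates), f"alpha={config.alpha}")
    logger.info("stage annotation: %d enriched terms -> %d candidate genes",
                len(enrichment), len(candidates))

    # stage 4: network filter (gene level)
    profile = centrality_profile(network)
    network_pass = top_fraction_filter(
        profile, candidates, config.q_degree, config.q_betweenness
    )
    _stage(
        "network_filter",
        len(network_pass),
        f"q_degree={config.q_degree}, q_betweenness={config.q_betweenness}",
    )
    logger.info("stage network: %d candidates -> %d genes", len(candidates), len(network_pass))

    # stage 5: expression filter (edge level)
    tau = ccrg_abs_pcc_threshold(edges, compendium, config.pcc_percentile)
    surviving = edges[
        edges["gene"].isin(network_pass) & (edges["pcc"].abs() >= tau)
    ].copy()
    _stage("expression_filter", len(surviving), f"tau={tau:.4g}")
    logger.info("stage expression: tau=%.4g -> %d surviving edges", tau, len(surviving))

    # stage 6: rank fusion on surviving genes
    fusion = fuse_gene_ranks(profile, sorted(surviving["gene"].unique()))
    predictions = surviving.merge(
        fusion, on="gene", how="inner", validate="many_to_one"
    )
    predictions["degree"] = predictions["gene"].map(profile["degree"]).astype(int)
    predictions["betweenness"] = predictions["gene"].map(profile["betweenness"])
    predictions["pass_go"] = True
    predictions["pass_network"] = True
    predictions["pass_pcc"] = True
    predictions = predictions[PREDICTION_COLUMNS].sort_values(
        ["drug", "q_score", "gene"], kind="mergesort", ignore_index=True
    )

    null_comparisons: dict = {}
    seed_class: list = []
    summary: dict = {}
    if characterize:
        seed_in_net = [g for g in seed_genes if g in profile.index]
        if len(seed_in_net) >= 2:
            for metric in ("degree", "betweenness"):
                null_comparisons[metric] = random_set_null_comparison(
                    profile, seed_in_net, metric,
                    n_perm=config.n_perm, seed=config.rng_seed,
                )
        seed_pccs = edges.loc[seed_edge_mask(edges, compendium), "pcc"]
        summary = pcc_distribution_summary(seed_pccs)
        try:
            seed_class = classify_seed_pairs(
                edges, compendium, z_threshold=config.z_threshold
            )
        except ValueError as exc:
            logger.warning("seed-pair classification skipped: %s", exc)

    return PipelineResult(
        predictions=predictions,
        edges=edges,
        undefined_edges=undefined,
        tau=tau,
        enrichment=enrichment,
        candidate_genes=candidates,
        network_pass_genes=network_pass,
        fusion=fusion,
        null_comparisons=null_comparisons,
        seed_pcc_summary=summary,
        seed_classification=seed_class,
        config=config,
    )


def run_baseline(edges: pd.DataFrame, k: int) -> pd.DataFrame:
    """Correlation-only comparator: the top-k |PCC| edges (matched count)."""
    return baseline_predictions(edges, k)


def write_manifest(result: PipelineResult, path: str | Path) -> None:
    """Serialize the run configuration and headline cardinalities as JSON."""
    Path(path).write_text(json.dumps(result.manifest(), indent=2, sort_keys=True))
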