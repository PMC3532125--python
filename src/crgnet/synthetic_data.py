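"""Seeded synthetic input bundles with planted ground truth.

Emulates the structure of a pharmacogenomic screen joined with a protein-
interaction network and an ontology annotation:

* a ~60-cell-line screen: a complete log-scale expression matrix and a
  gappy drug-activity (lgGI50-like) matrix;
* a scale-free-ish interaction network grown by preferential attachment,
  with the planted seed genes given an attachment bonus so their degree
  and betweenness exceed random genes (the hub/bottleneck property);
* a layered ontology DAG of depth >= 6 whose depth-5 terms carry the
  annotation, with seed genes concentrated into a few terms;
* a curated-pair compendium listing the planted drug-gene relationships.

Planted correlations use a Gaussian construction: a drug's activity is a
linear blend of its planted genes' standardized expression plus independent
noise, giving each planted pair its target population correlation exactly.
Target |r| values span a weak-to-strong range (default 0.1-0.6), so most
planted pairs sit in the weak-correlation regime a pure correlation screen
misses.  Activity entries are masked completely at random.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import AnnotationSet, CompendiumEntry, OntologyGraph

logger = logging.getLogger(__name__)

__all__ = [
    "FixtureSpec",
    "FixtureBundle",
    "generate_network",
    "generate_annotation",
    "generate_screen",
    "generate_fixture_bundle",
    "write_bundle",
    "synthetic_reference_compendium",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults mirror the scale of the emulated screen: a 60-cell-line panel,
    2000 measured genes, 50 assayed drugs, 40 seed genes documented in 60
    curated pairs with planted |correlations| spanning 0.1-0.6.
    """

    n_genes: int = 2000
    n_drugs: int = 50
    n_cells: int = 60
    n_seed_genes: int = 40
    n_seed_pairs: int = 60
    planted_pcc_range: tuple[float, float] = (0.1, 0.6)
    weak_fraction: float = 0.806  # share of planted pairs with |r| < 0.3
    hub_bias: float = 30.0
    n_terms: int = 120          # annotated terms at depth 5
    seed_term_count: int = 5    # depth-5 terms concentrating the seed genes
    seed_concentration: float = 1.0
    term_size_range: tuple[int, int] = (10, 40)
    missing_rate: float = 0.05
    pa_edges_per_node: int = 3
    dag_depth: int = 7
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 50:
            raise ValueError("n_genes must be >= 50")
        if self.n_seed_genes > self.n_genes:
            raise ValueError("n_seed_genes cannot exceed n_genes")
        if self.seed_term_count > self.n_terms:
            raise ValueError("seed_term_count cannot exceed n_terms")
        for name in ("missing_rate", "seed_concentration", "weak_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.planted_pcc_range
        if not 0 <= lo <= hi < 1:
            raise ValueError("planted_pcc_range must satisfy 0 <= lo <= hi < 1")
        if self.hub_bias < 0:
            raise ValueError("hub_bias must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    @property
    def drug_ids(self) -> list[str]:
        return [f"drug{i:03d}" for i in range(self.n_drugs)]

    @property
    def cell_ids(self) -> list[str]:
        return [f"CELL{i:02d}" for i in range(self.n_cells)]


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    expression: pd.DataFrame
    activity: pd.DataFrame
    network: nx.Graph
    annotation: AnnotationSet
    ontology: OntologyGraph
    compendium: list[CompendiumEntry]
    seed_genes: list[str]
    seed_terms: list[str]
    ground_truth: pd.DataFrame  # columns drug, gene, target_pcc


def _rng(spec: FixtureSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.rng_seed, salt]))


def generate_network(spec: FixtureSpec) -> tuple[nx.Graph, list[str]]:
    """Preferential-attachment network with centrality-boosted seed genes.

    Nodes join in random order, each attaching ``pa_edges_per_node`` edges
    to existing nodes with probability proportional to degree + 1 plus
    ``hub_bias`` for seed genes.  With hub_bias = 0 seed genes are
    exchangeable with the rest; large hub_bias makes them hubs and
    bottlenecks.  Returns the graph and the seed gene list.
    """
    rng = _rng(spec, 1)
    genes = spec.gene_ids
    seed_genes = sorted(rng.choice(genes, size=spec.n_seed_genes, replace=False))
    is_seed = np.zeros(spec.n_genes, dtype=bool)
    order = rng.permutation(spec.n_genes)
    gene_at = [genes[i] for i in order]
    seed_set = set(seed_genes)
    is_seed = np.array([g in seed_set for g in gene_at])

    m = spec.pa_edges_per_node
    degree = np.zeros(spec.n_genes)
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    # initial clique over the first m+1 arrivals
    for i in range(m + 1):
        for j in range(i):
            graph.add_edge(gene_at[i], gene_at[j])
            degree[i] += 1
            degree[j] += 1
    weight = np.zeros(spec.n_genes)
    for t in range(m + 1, spec.n_genes):
        active = t
        w = degree[:active] + 1.0 + spec.hub_bias * is_seed[:active]
        p = w / w.sum()
        targets = rng.choice(active, size=min(m, active), replace=False, p=p)
        for j in targets:
            graph.add_edge(gene_at[t], gene_at[j])
            degree[t] += 1
            degree[j] += 1
    return graph, list(seed_genes)


def generate_annotation(
    spec: FixtureSpec, seed_genes: list[str]
) -> tuple[AnnotationSet, OntologyGraph]:
    """Layered ontology DAG plus gene annotations at depths 4-6.

    Level widths grow toward depth 5, which holds the ``n_terms`` annotated
    terms; extra depth-4 and depth-6 annotated terms exercise the depth
    rule.  Every term's parents sit one level up, so its depth equals its
    level exactly.  Seed genes are planted into ``seed_term_count`` depth-5
    terms with probability ``seed_concentration``; all genes also receive
    uniform background annotations.
    """
    rng = _rng(spec, 2)
    genes = spec.gene_ids
    widths = [1, 3, 9, 27, 50, spec.n_terms] + [20] * (spec.dag_depth - 5)
    levels: list[list[str]] = []
    dag = nx.DiGraph()
    for depth, width in enumerate(widths):
        terms = [f"T:{depth}:{i:04d}" for i in range(width)]
        levels.append(terms)
        for term in terms:
            dag.add_node(term)
            if depth > 0:
                parents = rng.choice(
                    levels[depth - 1],
                    size=min(len(levels[depth - 1]), 1 + int(rng.random() < 0.3)),
                    replace=False,
                )
                for p in parents:
                    dag.add_edge(term, p)
    ontology = OntologyGraph(
        graph=dag, roots=frozenset(levels[0]), namespaces={t: "BP" for t in dag}
    )

    annotated_terms = levels[4] + levels[5] + levels[6]
    lo, hi = spec.term_size_range
    term_genes: dict[str, set[str]] = {}
    for term in annotated_terms:
        size = int(rng.integers(lo, hi + 1))
        term_genes[term] = set(rng.choice(genes, size=size, replace=False))
    seed_terms = [levels[5][i] for i in range(spec.seed_term_count)]
    for g in seed_genes:
        if rng.random() < spec.seed_concentration:
            k = 1 + int(rng.random() < 0.5)
            for term in rng.choice(seed_terms, size=k, replace=False):
                term_genes[term].add(g)
    annotation = AnnotationSet(
        term_genes={t: frozenset(g) for t, g in term_genes.items()},
        term_names={t: f"synthetic term {t}" for t in term_genes},
        term_namespaces={t: "BP" for t in term_genes},
    )
    return annotation, ontology


def generate_screen(
    spec: FixtureSpec, seed_genes: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, list[CompendiumEntry], pd.DataFrame]:
    """Expression and activity matrices with planted drug-gene correlations.

    Expression is iid standard normal per gene.  Each planted pair (d, g)
    gets a signed target correlation rho with |rho| spanning
    ``planted_pcc_range``; drug d's activity is sum_g rho_g z_g +
    sqrt(1 - sum rho^2) * noise, so each pair's population correlation is
    exactly rho (pairs of one drug use distinct genes).  Unplanted drugs
    are pure noise.  Activity entries are then masked at ``missing_rate``.
    Returns (expression, activity, compendium, ground_truth).
    """
    rng = _rng(spec, 3)
    genes, drugs, cells = spec.gene_ids, spec.drug_ids, spec.cell_ids
    expr = rng.standard_normal((spec.n_genes, spec.n_cells))
    expression = pd.DataFrame(expr, index=genes, columns=cells)

    # planted pairs: cycle seed genes across drugs; magnitudes span the range
    # but concentrate below 0.3 (weak_fraction), the weak-correlation regime
    # in which a pure correlation screen misses most documented pairs
    lo, hi = spec.planted_pcc_range
    split = min(0.3, hi)
    n_weak = int(round(spec.weak_fraction * spec.n_seed_pairs)) if hi > 0.3 else spec.n_seed_pairs
    mags = np.concatenate(
        [
            np.linspace(lo, split, n_weak, endpoint=False),
            np.linspace(split, hi, spec.n_seed_pairs - n_weak),
        ]
    )
    signs = rng.choice([-1.0, 1.0], size=spec.n_seed_pairs)
    order = rng.permutation(spec.n_seed_pairs)
    pair_rho = (mags * signs)[order]
    planted: dict[str, list[tuple[str, float]]] = {}
    truth_rows = []
    gi = 0
    for k in range(spec.n_seed_pairs):
        drug = drugs[k % spec.n_drugs]
        existing = {g for g, _ in planted.get(drug, [])}
        for _ in range(spec.n_seed_genes):
            gene = seed_genes[gi % len(seed_genes)]
            gi += 1
            if gene not in existing:
                break
        rho = float(pair_rho[k])
        budget = 1.0 - sum(r * r for _, r in planted.get(drug, []))
        if rho * rho >= budget:  # keep total explained variance < 1
            rho = float(np.sign(rho) * np.sqrt(max(budget - 1e-3, 0.0)))
        planted.setdefault(drug, []).append((gene, rho))
        truth_rows.append({"drug": drug, "gene": gene, "target_pcc": rho})

    zscore = (expr - expr.mean(axis=1, keepdims=True)) / expr.std(axis=1, keepdims=True)
    gene_row = {g: i for i, g in enumerate(genes)}
    act = np.empty((spec.n_drugs, spec.n_cells))
    for di, drug in enumerate(drugs):
        comps = planted.get(drug, [])
        signal = np.zeros(spec.n_cells)
        var = 0.0
        for gene, rho in comps:
            signal += rho * zscore[gene_row[gene]]
            var += rho * rho
        act[di] = signal + np.sqrt(max(1.0 - var, 0.0)) * rng.standard_normal(
            spec.n_cells
        )
    mask = rng.random(act.shape) < spec.missing_rate
    act[mask] = np.nan
    activity = pd.DataFrame(act, index=drugs, columns=cells)

    compendium = [
        CompendiumEntry(
            drug_name=row["drug"],
            gene_symbol=row["gene"],
            description=f"planted pair, target r={row['target_pcc']:+.3f}",
        )
        for row in truth_rows
    ]
    ground_truth = pd.DataFrame(truth_rows)
    return expression, activity, compendium, ground_truth


def generate_fixture_bundle(
    spec: FixtureSpec = FixtureSpec(), out_dir: str | Path | None = None
) -> FixtureBundle:
    """Generate a complete, internally consistent input bundle.

    The compendium's gene set is exactly the planted seed-gene set used for
    the network and annotation generators.  With ``out_dir`` the bundle is
    also written in the loader formats (see :func:`write_bundle`).
    """
    network, seed_genes = generate_network(spec)
    annotation, ontology = generate_annotation(spec, seed_genes)
    expression, activity, compendium, truth = generate_screen(spec, seed_genes)
    seed_terms = [f"T:5:{i:04d}" for i in range(spec.seed_term_count)]
    bundle = FixtureBundle(
        spec=spec,
        expression=expression,
        activity=activity,
        network=network,
        annotation=annotation,
        ontology=ontology,
        compendium=compendium,
        seed_genes=seed_genes,
        seed_terms=seed_terms,
        ground_truth=truth,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: FixtureBundle, out_dir: str | Path) -> None:
    """Write every bundle component in the formats the loaders read."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.expression.to_csv(out / "expression.tsv", sep="\t", float_format="%.10g")
    bundle.activity.to_csv(
        out / "activity.tsv", sep="\t", float_format="%.10g", na_rep="NaN"
    )
    with (out / "network.tsv").open("w") as fh:
        for a, b in sorted(bundle.network.edges()):
            fh.write(f"{a}\t{b}\n")
    with (out / "annotation.gmt").open("w") as fh:
        for term in sorted(bundle.annotation.term_genes):
            genes = "\t".join(sorted(bundle.annotation.term_genes[term]))
            name = bundle.annotation.term_names.get(term, "")
            fh.write(f"{term}\t{name}\t{genes}\n")
    with (out / "ontology.tsv").open("w") as fh:
        for child, parent in sorted(bundle.ontology.graph.edges()):
            fh.write(f"{child}\t{parent}\n")
    comp = pd.DataFrame(
        [
            {
                "drug": e.drug_name,
                "gene": e.gene_symbol,
                "cell_line": e.cell_line or "",
                "pmid": e.pmid or "",
                "description": e.description or "",
            }
            for e in bundle.compendium
        ]
    )
    comp.to_csv(out / "compendium.tsv", sep="\t", index=False)
    bundle.ground_truth.to_csv(
        out / "ground_truth.tsv", sep="\t", index=False, float_format="%.10g"
    )
    (out / "manifest.json").write_text(
        json.dumps(asdict(bundle.spec), indent=2, sort_keys=True)
    )


def synthetic_reference_compendium() -> list[CompendiumEntry]:
    """Deterministic synthetic stand-in for a curated drug-gene compendium.

    Purely synthetic identifiers arranged to the documented cardinality of
    the curated resource this schema models: 150 distinct drug-gene pairs
    covering 64 drugs and 94 genes, each with a cell line, a placeholder
    PubMed id and a description.
    """
    drugs = [f"drug-{i:02d}" for i in range(64)]
    genes = [f"SYNGENE{i:02d}" for i in range(94)]
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    # cover every gene and every drug first, then fill deterministically
    for i in range(94):
        pairs.append((drugs[i % 64], genes[i]))
        seen.add(pairs[-1])
    step, j = 0, 0
    while len(pairs) < 150:
        cand = (drugs[j % 64], genes[(j * 7 + step) % 94])
        j += 1
        if j % 64 == 0:
            step += 3
        if cand not in seen:
            seen.add(cand)
            pairs.append(cand)
    return [
        CompendiumEntry(
            drug_name=d,
            gene_symbol=g,
            cell_line=f"CELL{k % 60:02d}",
            pmid=10_000_000 + k,
            description="synthetic curated relationship",
        )
        for k, (d, g) in enumerate(pairs)
    ]
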