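"""Readers and writers for the pipeline's input and output formats.

All tabular inputs are UTF-8 tab-separated text: expression and drug-activity
matrices (header row of cell-line ids, leading id column), protein-interaction
edge lists, gene-set files in GMT dialect, ontology parent links (OBO 1.2
subset or two-column TSV), and the curated drug-gene compendium.  Parsing,
deduplication and identifier normalization happen here; no statistics.

Gene and drug identity is resolved case-insensitively after whitespace
trimming.  No alias/synonym resolution is attempted: symbols that differ
textually are different genes.  This is deterministic but means upstream
identifier harmonization is the caller's responsibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CompendiumEntry",
    "AnnotationSet",
    "OntologyGraph",
    "DataFormatError",
    "load_expression_matrix",
    "load_activity_matrix",
    "load_network",
    "load_gene_sets",
    "load_ontology_graph",
    "load_compendium",
    "compendium_summary",
    "write_predictions",
    "align_cell_lines",
    "normalize_gene",
    "normalize_drug",
    "PREDICTION_COLUMNS",
]

#: Column schema of the prediction table written by :func:`write_predictions`.
PREDICTION_COLUMNS = [
    "drug",
    "gene",
    "pcc",
    "n_complete",
    "degree",
    "betweenness",
    "rank_ratio_degree",
    "rank_ratio_betweenness",
    "q_score",
    "pass_go",
    "pass_network",
    "pass_pcc",
]

DEFAULT_MISSING_TOKENS = ("NaN", "NA", "")


class DataFormatError(ValueError):
    """Raised when an input file violates the expected format."""


def normalize_gene(symbol: str) -> str:
    """Uppercased, whitespace-trimmed gene symbol."""
    return symbol.strip().upper()


def normalize_drug(name: str) -> str:
    """Lowercased, whitespace-trimmed drug name."""
    return name.strip().lower()


@dataclass(frozen=True)
class CompendiumEntry:
    """One curated drug-gene chemosensitivity relationship.

    ``(drug_name, gene_symbol)`` after normalization is the identity key;
    cell line, PubMed id and free-text description are provenance only.
    """

    drug_name: str
    gene_symbol: str
    cell_line: str | None = None
    pmid: int | None = None
    description: str | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (normalize_drug(self.drug_name), normalize_gene(self.gene_symbol))


@dataclass
class AnnotationSet:
    """Term -> gene-set map (GMT contents), with optional names/namespaces."""

    term_genes: dict[str, frozenset[str]]
    term_names: dict[str, str] = field(default_factory=dict)
    term_namespaces: dict[str, str] = field(default_factory=dict)

    def terms(self) -> list[str]:
        return list(self.term_genes)

    def annotated_genes(self) -> frozenset[str]:
        """Union of all gene sets: genes with at least one annotation."""
        out: set[str] = set()
        for genes in self.term_genes.values():
            out |= genes
        return frozenset(out)

    def restrict_to(self, genes: Iterable[str]) -> "AnnotationSet":
        """New set with every term intersected with *genes*; empty terms drop."""
        keep = frozenset(normalize_gene(g) for g in genes)
        tg = {}
        for term, gs in self.term_genes.items():
            inter = gs & keep
            if inter:
                tg[term] = inter
        return AnnotationSet(
            term_genes=tg,
            term_names={t: n for t, n in self.term_names.items() if t in tg},
            term_namespaces={t: n for t, n in self.term_namespaces.items() if t in tg},
        )


@dataclass
class OntologyGraph:
    """Ontology DAG as child->parent links with auto-detected roots."""

    graph: nx.DiGraph  # edges point child -> parent
    roots: frozenset[str]
    namespaces: dict[str, str] = field(default_factory=dict)

    def __contains__(self, term: str) -> bool:
        return term in self.graph


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def _read_matrix(path: str | Path, na_values: Sequence[str] | None) -> pd.DataFrame:
    path = Path(path)
    header = path.open(encoding="utf-8").readline().rstrip("\n").split("\t")
    cell_ids = [c.strip() for c in header[1:]]
    dupes = pd.Index(cell_ids)[pd.Index(cell_ids).duplicated()].unique()
    if len(dupes):
        raise DataFormatError(f"{path}: duplicate cell-line ids {list(dupes)}")
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=list(na_values) if na_values else [],
        keep_default_na=False,
        dtype=str,
    )
    df.columns = cell_ids
    df.index = df.index.astype(str).str.strip()
    # locate non-numeric cells precisely so the error names row and column
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & df.notna() & (df != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataFormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at row "
            f"{df.index[r]!r}, column {df.columns[c]!r}"
        )
    if na_values is not None:
        numeric[df.isna() | (df == "")] = np.nan
    return numeric.astype(float)


def load_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Load a genes x cell-lines expression matrix (log-scale intensities).

    Duplicate gene rows (e.g. multiple probes per symbol) are collapsed by
    their mean, which is logged.  All values must be finite and at least
    three cell-line columns must be present.
    """
    df = _read_matrix(path, na_values=None)
    if df.shape[1] < 3:
        raise DataFormatError(f"{path}: need >= 3 cell-line columns, got {df.shape[1]}")
    if df.isna().to_numpy().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise DataFormatError(
            f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}; "
            "expression matrices must be complete"
        )
    df.index = df.index.map(normalize_gene)
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by mean", n_dup)
        df = df.groupby(level=0, sort=False).mean()
    if not np.isfinite(df.to_numpy()).all():
        raise DataFormatError(f"{path}: non-finite expression values")
    return df


def load_activity_matrix(
    path: str | Path,
    missing_token: str | Sequence[str] = DEFAULT_MISSING_TOKENS,
    cell_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Load a drugs x cell-lines activity matrix (lgGI50) with explicit gaps.

    Missing entries (``missing_token``, default any of ``NaN``/``NA``/empty)
    become ``numpy.nan``.  Rows are kept even if fully missing; screening
    them out is a later, explicit filtering step.
    """
    tokens = [missing_token] if isinstance(missing_token, str) else list(missing_token)
    df = _read_matrix(path, na_values=tokens)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise DataFormatError(f"{path}: duplicate drug ids {dupes}")
    if int(df.notna().to_numpy().sum()) == 0:
        raise DataFormatError(f"{path}: no usable (non-missing) activity values")
    if cell_order is not None:
        present = [c for c in cell_order if c in df.columns]
        if not present:
            raise DataFormatError(f"{path}: no cell lines overlap the reference order")
        df = df[present]
    return df


def align_cell_lines(
    expression: pd.DataFrame, activity: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both matrices to shared cell lines, in expression order."""
    shared = [c for c in expression.columns if c in set(activity.columns)]
    if not shared:
        raise DataFormatError("expression and activity share no cell lines")
    dropped = (expression.shape[1] - len(shared), activity.shape[1] - len(shared))
    if any(dropped):
        logger.info(
            "cell-line alignment dropped %d expression / %d activity columns", *dropped
        )
    return expression[shared], activity[shared]


# ---------------------------------------------------------------------------
# network / gene sets / ontology
# ---------------------------------------------------------------------------


def load_network(path: str | Path) -> nx.Graph:
    """Load an undirected protein-interaction network from an edge-list TSV.

    The first two columns are interactor gene symbols; extra columns are
    ignored.  Self-loops and duplicate (a,b)/(b,a) records are dropped with
    counts logged.
    """
    path = Path(path)
    graph = nx.Graph()
    n_self = n_dup = n_rows = 0
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DataFormatError(f"{path}: edge line with <2 columns: {line!r}")
            a, b = normalize_gene(fields[0]), normalize_gene(fields[1])
            n_rows += 1
            if a == b:
                n_self += 1
                continue
            if graph.has_edge(a, b):
                n_dup += 1
                continue
            graph.add_edge(a, b)
    if n_rows == 0:
        raise DataFormatError(f"{path}: empty edge list")
    if graph.number_of_edges() == 0:
        raise DataFormatError(f"{path}: empty network after cleaning")
    if n_self or n_dup:
        logger.info("dropped %d self-loops and %d duplicate edges", n_self, n_dup)
    return graph


def load_gene_sets(path: str | Path) -> AnnotationSet:
    """Load term -> gene-set annotations from a GMT file.

    GMT dialect: ``term_id<TAB>description<TAB>gene1<TAB>gene2...``.  Genes
    are normalized and deduplicated within a term; repeated term ids take
    the union of their gene sets (warned).  Lines with fewer than three
    fields are skipped with a warning.
    """
    path = Path(path)
    term_genes: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    n_skipped = 0
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                n_skipped += 1
                logger.warning("%s: skipping malformed GMT line %r", path, line[:60])
                continue
            term, desc = fields[0].strip(), fields[1].strip()
            genes = {normalize_gene(g) for g in fields[2:] if g.strip()}
            if term in term_genes:
                logger.warning("%s: repeated term %s; taking union", path, term)
                term_genes[term] |= genes
            else:
                term_genes[term] = genes
                names[term] = desc
    if not term_genes:
        raise DataFormatError(f"{path}: no valid GMT lines")
    return AnnotationSet(
        term_genes={t: frozenset(g) for t, g in term_genes.items()},
        term_names=names,
    )


def _validate_dag(graph: nx.DiGraph, source: str) -> frozenset[str]:
    if graph.number_of_nodes() == 0:
        raise DataFormatError(f"{source}: empty ontology")
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise DataFormatError(
            f"{source}: ontology contains a cycle through {cycle[0][0]!r}"
        )
    roots = frozenset(n for n in graph if graph.out_degree(n) == 0)
    if not roots:
        raise DataFormatError(f"{source}: no root term found")
    return roots


def load_ontology_graph(path: str | Path) -> OntologyGraph:
    """Load an ontology DAG from OBO (``is_a``/``part_of``) or 2-column TSV.

    Edges point child -> parent.  Roots are auto-detected as the parentless
    terms; a cycle anywhere is an error naming one member.
    """
    path = Path(path)
    graph = nx.DiGraph()
    namespaces: dict[str, str] = {}
    if path.suffix.lower() == ".obo":
        multi = obonet.read_obo(path)
        for term, data in multi.nodes(data=True):
            graph.add_node(term)
            if "namespace" in data:
                namespaces[term] = data["namespace"]
        for child, parent, key in multi.edges(keys=True):
            if key in ("is_a", "part_of"):
                graph.add_edge(child, parent)
    else:
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise DataFormatError(f"{path}: link line with <2 columns: {line!r}")
                child, parent = fields[0].strip(), fields[1].strip()
                graph.add_edge(child, parent)
    roots = _validate_dag(graph, str(path))
    return OntologyGraph(graph=graph, roots=roots, namespaces=namespaces)


# ---------------------------------------------------------------------------
# compendium
# ---------------------------------------------------------------------------


def load_compendium(
    path: str | Path,
    drug_col: str | None = None,
    gene_col: str | None = None,
) -> list[CompendiumEntry]:
    """Load curated drug-gene pairs from a TSV with a header row.

    Column names are matched case-insensitively; ``drug_col``/``gene_col``
    override auto-detection (``drug``/``drug_name``, ``gene``/``gene_symbol``).
    Pairs are deduplicated on the normalized (drug, gene) key; rows missing
    either field are rejected with a warning.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    cols = {c.lower().strip(): c for c in df.columns}

    def pick(explicit: str | None, candidates: Sequence[str], what: str) -> str:
        if explicit is not None:
            if explicit.lower() not in cols:
                raise DataFormatError(f"{path}: no {what} column {explicit!r}")
            return cols[explicit.lower()]
        for cand in candidates:
            if cand in cols:
                return cols[cand]
        raise DataFormatError(f"{path}: missing {what} column (tried {candidates})")

    dcol = pick(drug_col, ("drug", "drug_name"), "drug")
    gcol = pick(gene_col, ("gene", "gene_symbol"), "gene")
    ccol = next((cols[c] for c in ("cell_line", "cell line", "cellline") if c in cols), None)
    pcol = next((cols[c] for c in ("pmid", "pubmed", "pubmed_id") if c in cols), None)
    xcol = next((cols[c] for c in ("description", "desc", "note") if c in cols), None)

    seen: set[tuple[str, str]] = set()
    entries: list[CompendiumEntry] = []
    for _, row in df.iterrows():
        drug, gene = row[dcol].strip(), row[gcol].strip()
        if not drug or not gene:
            logger.warning("%s: rejecting row with empty drug or gene", path)
            continue
        pmid = None
        if pcol and row[pcol].strip():
            try:
                pmid = int(float(row[pcol]))
            except ValueError:
                logger.warning("%s: unparsable pmid %r", path, row[pcol])
        entry = CompendiumEntry(
            drug_name=drug,
            gene_symbol=gene,
            cell_line=(row[ccol].strip() or None) if ccol else None,
            pmid=pmid,
            description=(row[xcol].strip() or None) if xcol else None,
        )
        if entry.key in seen:
            continue
        seen.add(entry.key)
        entries.append(entry)
    return entries


class CompendiumSummary(NamedTuple):
    n_pairs: int
    n_drugs: int
    n_genes: int


def compendium_summary(entries: Iterable[CompendiumEntry]) -> CompendiumSummary:
    """Distinct (pair, drug, gene) counts over normalized identifiers."""
    keys = {e.key for e in entries}
    return CompendiumSummary(
        n_pairs=len(keys),
        n_drugs=len({d for d, _ in keys}),
        n_genes=len({g for _, g in keys}),
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_predictions(table: pd.DataFrame, path: str | Path) -> None:
    """Write a prediction table as TSV in deterministic row order.

    Rows sort by (drug asc, q_score asc, gene asc); floats are printed with
    10 significant digits so a reload reproduces values to textual precision.
    """
    out = table.copy()
    for col in PREDICTION_COLUMNS:
        if col not in out.columns:
            raise ValueError(f"prediction table missing column {col!r}")
    out = out[PREDICTION_COLUMNS]
    out = out.sort_values(["drug", "q_score", "gene"], kind="mergesort")
    out.to_csv(Path(path), sep="\t", index=False, float_format="%.10g")
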