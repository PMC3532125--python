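import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from crgnet.data_io import (
    CompendiumEntry,
    DataFormatError,
    compendium_summary,
    load_activity_matrix,
    load_compendium,
    load_expression_matrix,
    load_gene_sets,
    load_network,
    load_ontology_graph,
    write_predictions,
    PREDICTION_COLUMNS,
)
from crgnet.go_filter import term_depth


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestExpressionMatrix:
    def test_identity_parse(self, tmp_path):
        p = _write(
            tmp_path,
            "e.tsv",
            "id\tc1\tc2\tc3\tc4\ng1\t1\t2\t3\t4\ng2\t5\t6\t7\t8\ng3\t9\t1\t2\t3\n",
        )
        m = load_expression_matrix(p)
        assert m.shape == (3, 4)
        assert m.loc["G1", "c3"] == 3.0

    def test_duplicate_gene_rows_collapse_by_mean(self, tmp_path):
        p = _write(
            tmp_path,
            "e.tsv",
            "id\tc1\tc2\tc3\tc4\ng1\t1\t2\t3\t4\ng1\t3\t4\t5\t6\n",
        )
        m = load_expression_matrix(p)
        assert m.shape == (1, 4)
        assert m.loc["G1"].tolist() == [2.0, 3.0, 4.0, 5.0]

    def test_non_numeric_cell_names_location(self, tmp_path):
        p = _write(
            tmp_path, "e.tsv", "id\tc1\tc2\tc3\ng1\t1\tabc\t3\ng2\t4\t5\t6\n"
        )
        with pytest.raises(DataFormatError, match="abc.*g1.*c2"):
            load_expression_matrix(p)

    def test_duplicate_cell_id_rejected(self, tmp_path):
        p = _write(tmp_path, "e.tsv", "id\tc1\tc1\tc2\ng1\t1\t2\t3\n")
        with pytest.raises(DataFormatError, match="duplicate cell-line"):
            load_expression_matrix(p)


class TestActivityMatrix:
    def test_missing_tokens_flagged(self, tmp_path):
        p = _write(
            tmp_path, "a.tsv", "id\tc1\tc2\tc3\nd1\t1.2\tNaN\t3.0\nd2\t1\t2\t3\n"
        )
        m = load_activity_matrix(p)
        assert math.isnan(m.loc["d1", "c2"])
        assert m.notna().sum().sum() == 5

    def test_all_missing_row_retained(self, tmp_path):
        p = _write(
            tmp_path, "a.tsv", "id\tc1\tc2\nd1\tNaN\tNA\nd2\t1\t2\n"
        )
        m = load_activity_matrix(p)
        assert m.loc["d1"].isna().all()
        assert "d1" in m.index

    def test_custom_missing_token(self, tmp_path):
        p = _write(tmp_path, "a.tsv", "id\tc1\tc2\nd1\t1\tMISS\n")
        m = load_activity_matrix(p, missing_token="MISS")
        assert math.isnan(m.loc["d1", "c2"])


class TestNetwork:
    def test_dedup_and_self_loop_removal(self, tmp_path):
        p = _write(tmp_path, "n.tsv", "a\tb\nb\ta\nb\tb\na\tc\n")
        g = load_network(p)
        assert g.number_of_edges() == 2
        assert set(g.nodes()) == {"A", "B", "C"}

    def test_single_edge(self, tmp_path):
        p = _write(tmp_path, "n.tsv", "x\ty\n")
        g = load_network(p)
        assert g.number_of_edges() == 1 and g.number_of_nodes() == 2

    def test_only_self_loops_is_error(self, tmp_path):
        p = _write(tmp_path, "n.tsv", "x\tx\ny\ty\n")
        with pytest.raises(DataFormatError, match="empty network after cleaning"):
            load_network(p)

    def test_idempotent_roundtrip(self, tmp_path, small_bundle):
        out = tmp_path / "net.tsv"
        with out.open("w") as fh:
            for a, b in sorted(small_bundle.network.edges()):
                fh.write(f"{a}\t{b}\n")
        g = load_network(out)
        assert nx.utils.graphs_equal(
            nx.Graph(g.edges()), nx.Graph(small_bundle.network.edges())
        )


class TestGeneSets:
    def test_within_term_dedup(self, tmp_path):
        p = _write(tmp_path, "s.gmt", "GO:1\tdesc\tA\tB\tA\n")
        ann = load_gene_sets(p)
        assert ann.term_genes["GO:1"] == {"A", "B"}

    def test_repeated_term_union(self, tmp_path):
        p = _write(tmp_path, "s.gmt", "GO:1\td\tA\tB\nGO:1\td\tB\tC\n")
        ann = load_gene_sets(p)
        assert ann.term_genes["GO:1"] == {"A", "B", "C"}

    def test_malformed_line_skipped(self, tmp_path):
        p = _write(tmp_path, "s.gmt", "GO:1\tdesc\tA\nbad_line\tonly2\n")
        ann = load_gene_sets(p)
        assert list(ann.term_genes) == ["GO:1"]

    def test_all_lines_bad_is_error(self, tmp_path):
        p = _write(tmp_path, "s.gmt", "x\ty\n")
        with pytest.raises(DataFormatError):
            load_gene_sets(p)


class TestOntology:
    def test_chain_depths(self, tmp_path):
        p = _write(tmp_path, "o.tsv", "t1\tr\nt2\tt1\n")
        ont = load_ontology_graph(p)
        assert ont.roots == {"r"}
        assert [term_depth(ont, t) for t in ("r", "t1", "t2")] == [0, 1, 2]

    def test_diamond_is_valid_dag(self, tmp_path):
        p = _write(tmp_path, "o.tsv", "a\tr\nb\tr\nc\ta\nc\tb\n")
        ont = load_ontology_graph(p)
        assert term_depth(ont, "c") == 2

    def test_cycle_detected(self, tmp_path):
        p = _write(tmp_path, "o.tsv", "a\tb\nb\ta\n")
        with pytest.raises(DataFormatError, match="cycle"):
            load_ontology_graph(p)

    def test_obo_subset(self, tmp_path):
        obo = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: root\nnamespace: biological_process\n\n"
            "[Term]\nid: GO:0000002\nname: child\nnamespace: biological_process\n"
            "is_a: GO:0000001 ! root\n"
        )
        p = _write(tmp_path, "o.obo", obo)
        ont = load_ontology_graph(p)
        assert ont.roots == {"GO:0000001"}
        assert term_depth(ont, "GO:0000002") == 1


class TestCompendium:
    def test_dedup_on_pair_key(self, tmp_path):
        p = _write(
            tmp_path,
            "c.tsv",
            "drug\tgene\nTaxol\tTP53\ntaxol \ttp53\ncisplatin\tERCC1\n",
        )
        entries = load_compendium(p)
        assert len(entries) == 2

    def test_empty_gene_rejected(self, tmp_path):
        p = _write(tmp_path, "c.tsv", "drug\tgene\nTaxol\t\nx\tY\n")
        entries = load_compendium(p)
        assert len(entries) == 1

    def test_missing_column_is_error(self, tmp_path):
        p = _write(tmp_path, "c.tsv", "drug\tnotgene\nTaxol\tX\n")
        with pytest.raises(DataFormatError, match="gene"):
            load_compendium(p)

    def test_summary_counts(self):
        entries = [
            CompendiumEntry("d1", "g1"),
            CompendiumEntry("d1", "g2"),
            CompendiumEntry("d2", "g1"),
        ]
        assert compendium_summary(entries) == (3, 2, 2)
        assert compendium_summary([]) == (0, 0, 0)

    def test_summary_never_exceeds_row_count(self, tmp_path):
        rows = ["drug\tgene"] + [f"d{i%3}\tg{i%4}" for i in range(20)]
        p = _write(tmp_path, "c.tsv", "\n".join(rows) + "\n")
        entries = load_compendium(p)
        n_pairs, n_drugs, n_genes = compendium_summary(entries)
        assert n_pairs <= 20 and n_drugs <= n_pairs and n_genes <= n_pairs


class TestPredictionsOutput:
    @staticmethod
    def _table(n=1):
        rows = []
        for i in range(n):
            rows.append(
                dict(
                    drug=f"d{i%2}", gene=f"g{i}", pcc=0.1 * i - 0.3, n_complete=50,
                    degree=5 + i, betweenness=1.5 * i,
                    rank_ratio_degree=0.2, rank_ratio_betweenness=0.4,
                    q_score=0.1 + 0.01 * i,
                    pass_go=True, pass_network=True, pass_pcc=True,
                )
            )
        return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)

    def test_roundtrip_and_determinism(self, tmp_path):
        t = self._table(7)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_predictions(t, p1)
        write_predictions(t.sample(frac=1, random_state=3), p2)  # shuffled input
        assert p1.read_bytes() == p2.read_bytes()
        back = pd.read_csv(p1, sep="\t")
        merged = back.merge(t, on=["drug", "gene"], suffixes=("_r", ""))
        assert np.allclose(merged["pcc_r"], merged["pcc"], rtol=1e-9)

    def test_empty_table_header_only(self, tmp_path):
        p = tmp_path / "e.tsv"
        write_predictions(self._table(0), p)
        assert p.read_text().strip() == "\t".join(PREDICTION_COLUMNS)
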