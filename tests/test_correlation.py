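import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crgnet.correlation import (
    build_edge_table,
    ccrg_abs_pcc_threshold,
    classify_seed_pairs,
    drug_null_z,
    filter_drugs_by_missingness,
    pairwise_pcc,
    pcc_distribution_summary,
)
from crgnet.data_io import CompendiumEntry


class TestMissingnessFilter:
    @staticmethod
    def _acts(missing_counts, n_cells=60):
        rows = {}
        for i, miss in enumerate(missing_counts):
            row = np.arange(n_cells, dtype=float)
            row[:miss] = np.nan
            rows[f"d{i}"] = row
        return pd.DataFrame.from_dict(rows, orient="index")

    def test_strictly_above_threshold_removed(self):
        acts = self._acts([49, 10])
        kept = filter_drugs_by_missingness(acts, 0.8)  # 49/60 = 0.817 > 0.8
        assert list(kept.index) == ["d1"]

    def test_exactly_at_threshold_retained(self):
        acts = self._acts([48, 10])  # 48/60 = 0.8 exactly
        kept = filter_drugs_by_missingness(acts, 0.8)
        assert set(kept.index) == {"d0", "d1"}

    def test_all_removed_is_error(self):
        acts = self._acts([59, 59])
        with pytest.raises(ValueError):
            filter_drugs_by_missingness(acts, 0.8)


class TestPairwisePcc:
    def test_perfect_positive_and_negative(self):
        assert pairwise_pcc([1, 2, 3], [2, 4, 6], min_complete=3)[0] == pytest.approx(1.0)
        assert pairwise_pcc([1, 2, 3], [6, 4, 2], min_complete=3)[0] == pytest.approx(-1.0)

    def test_gaps_use_complete_pairs_only(self):
        x = [1.0, 2.0, np.nan, 4.0]
        y = [2.0, 1.0, 5.0, 3.0]
        pcc, n = pairwise_pcc(x, y, min_complete=3)
        expected = np.corrcoef([1, 2, 4], [2, 1, 3])[0, 1]
        assert n == 3
        assert pcc == pytest.approx(expected, abs=1e-12)

    def test_closed_form_agreement_gap_free(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x, y = rng.standard_normal(30), rng.standard_normal(30)
            pcc, n = pairwise_pcc(x, y, min_complete=3)
            assert n == 30
            assert pcc == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_undefined_below_min_complete_or_zero_variance(self):
        pcc, n = pairwise_pcc([1, 2, np.nan], [1, 2, 3], min_complete=3)
        assert math.isnan(pcc) and n == 2
        pcc, _ = pairwise_pcc([1, 1, 1], [1, 2, 3], min_complete=3)
        assert math.isnan(pcc)

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            pairwise_pcc([1, 2], [1, 2, 3])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False),
                st.floats(-50, 50, allow_nan=False),
            ),
            min_size=5,
            max_size=30,
        ),
        scale=st.floats(0.1, 10),
        shift=st.floats(-5, 5),
    )
    def test_symmetry_affine_invariance_and_sign_flip(self, data, scale, shift):
        x = np.array([a for a, _ in data])
        y = np.array([b for _, b in data])
        p_xy, _ = pairwise_pcc(x, y, min_complete=5)
        p_yx, _ = pairwise_pcc(y, x, min_complete=5)
        if math.isnan(p_xy):
            assert math.isnan(p_yx)
            return
        assert p_xy == pytest.approx(p_yx, abs=1e-12)
        p_scaled, _ = pairwise_pcc(scale * x + shift, y, min_complete=5)
        assert p_scaled == pytest.approx(p_xy, abs=1e-7)
        p_neg, _ = pairwise_pcc(x, -y, min_complete=5)
        assert p_neg == pytest.approx(-p_xy, abs=1e-12)


class TestEdgeTable:
    def test_cardinality_no_gaps(self):
        cells = [f"c{i}" for i in range(12)]
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.standard_normal((3, 12)), index=list("abc"), columns=cells)
        acts = pd.DataFrame(rng.standard_normal((2, 12)), index=["d1", "d2"], columns=cells)
        edges, undefined = build_edge_table(acts, expr, min_complete=10)
        assert len(edges) == 6 and len(undefined) == 0

    def test_constant_drug_goes_undefined(self):
        cells = [f"c{i}" for i in range(12)]
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.standard_normal((2, 12)), index=["a", "b"], columns=cells)
        acts = pd.DataFrame(
            [[1.0] * 12, rng.standard_normal(12)], index=["flat", "ok"], columns=cells
        )
        edges, undefined = build_edge_table(acts, expr, min_complete=10)
        assert set(edges["drug"]) == {"ok"}
        assert set(undefined.loc[undefined["drug"] == "flat", "reason"]) == {
            "zero_variance_drug"
        }

    def test_planted_correlation_recovered(self, default_bundle):
        b = default_bundle
        edges, _ = build_edge_table(b.activity, b.expression, min_complete=10)
        strong = b.ground_truth[b.ground_truth["target_pcc"].abs() >= 0.5]
        merged = strong.merge(edges, on=["drug", "gene"])
        assert len(merged) == len(strong)
        tol = 3 / np.sqrt(merged["n_complete"] - 3)
        assert (np.abs(merged["pcc"] - merged["target_pcc"]) < tol).all()


class TestSeedPccThreshold:
    @staticmethod
    def _edges(abs_pccs):
        return pd.DataFrame(
            {
                "drug": [f"d{i}" for i in range(len(abs_pccs))],
                "gene": [f"g{i}" for i in range(len(abs_pccs))],
                "pcc": abs_pccs,
                "n_complete": 60,
            }
        )

    @staticmethod
    def _seeds(n):
        return [CompendiumEntry(f"d{i}", f"g{i}") for i in range(n)]

    def test_nearest_rank_fifth_percentile(self):
        vals = [0.05 * k for k in range(1, 21)]  # 0.05 .. 1.0
        tau = ccrg_abs_pcc_threshold(self._edges(vals), self._seeds(20), 5)
        assert tau == pytest.approx(0.05)

    def test_all_equal(self):
        tau = ccrg_abs_pcc_threshold(self._edges([0.3] * 8), self._seeds(8), 5)
        assert tau == pytest.approx(0.3)

    def test_at_least_95_percent_pass(self, small_bundle):
        from crgnet.correlation import seed_edge_mask

        b = small_bundle
        edges, _ = build_edge_table(b.activity, b.expression, min_complete=10)
        tau = ccrg_abs_pcc_threshold(edges, b.compendium, 5)
        seed_abs = edges.loc[seed_edge_mask(edges, b.compendium), "pcc"].abs()
        n = len(seed_abs)
        assert (seed_abs >= tau).sum() >= math.ceil(0.95 * n)

    def test_monotone_in_percentile(self):
        rng = np.random.default_rng(3)
        vals = rng.random(37)
        edges, seeds = self._edges(vals), self._seeds(37)
        taus = [ccrg_abs_pcc_threshold(edges, seeds, p) for p in (0, 1, 5, 10, 50, 100)]
        assert taus == sorted(taus)

    def test_no_seed_with_defined_pcc_is_error(self):
        with pytest.raises(ValueError, match="no seed pair"):
            ccrg_abs_pcc_threshold(self._edges([0.1]), [CompendiumEntry("zz", "yy")], 5)


class TestDrugNullZ:
    def test_z_zero_is_random(self):
        pccs = np.linspace(-0.5, 0.5, 40)
        res = drug_null_z("d", "g", 0.0, pccs)
        assert res.z == pytest.approx(0.0)
        assert res.label == "random"

    def test_population_sd_arithmetic(self):
        pccs = [-0.2, 0.0, 0.2] * 10  # mu=0, population sd=sqrt(2/75)... use exact
        res = drug_null_z("d", "g", 0.2, pccs)
        expected = abs(0.2 - 0.0) / np.std(pccs)
        assert res.z == pytest.approx(expected, abs=1e-12)
        assert res.label == "larger"

    def test_classes_partition_seed_pairs(self, small_bundle):
        b = small_bundle
        edges, _ = build_edge_table(b.activity, b.expression, min_complete=10)
        results = classify_seed_pairs(edges, b.compendium)
        labels = [r.label for r in results]
        assert set(labels) <= {"larger", "smaller", "random"}
        from crgnet.correlation import seed_edge_mask

        assert len(results) == int(seed_edge_mask(edges, b.compendium).sum())

    def test_planted_strong_positive_pair_is_larger(self, default_bundle):
        b = default_bundle
        edges, _ = build_edge_table(b.activity, b.expression, min_complete=10)
        strongest = b.ground_truth.loc[b.ground_truth["target_pcc"].idxmax()]
        drug_pccs = edges.loc[edges["drug"] == strongest["drug"], "pcc"].to_numpy()
        row = edges[(edges["drug"] == strongest["drug"]) & (edges["gene"] == strongest["gene"])]
        res = drug_null_z(strongest["drug"], strongest["gene"], float(row["pcc"].iloc[0]), drug_pccs)
        assert res.label == "larger"

    def test_degenerate_null_is_error(self):
        with pytest.raises(ValueError):
            drug_null_z("d", "g", 0.1, [0.2] * 40)


class TestPccSummary:
    def test_hand_counted_bands(self):
        s = pcc_distribution_summary([-0.1, 0.2, 0.6])
        assert s["bands"][0.3] == pytest.approx(2 / 3)
        assert s["bands"][0.5] == pytest.approx(2 / 3)

    def test_all_zero(self):
        s = pcc_distribution_summary([0.0] * 5)
        assert s["bands"][0.3] == 1.0 and s["bands"][0.5] == 1.0

    def test_empty_summary(self):
        s = pcc_distribution_summary([])
        assert s["n"] == 0 and s["bands"] == {}
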