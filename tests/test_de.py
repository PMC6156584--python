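import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dropcell import de
from dropcell.de import (bh_adjust, bulk_vs_sc_comparison, find_degs,
                         find_markers, reversal_analysis, two_part_lrt,
                         two_part_lrt_table)

from conftest import make_meta, make_norm
from oracles import oracle_two_part_stat


def zero_inflated(rng, n, zero_rate=0.35, min_pos=2):
    while True:
        x = rng.lognormal(0.5, 0.6, n)
        x[rng.random(n) < zero_rate] = 0.0
        if (x > 0).sum() >= min_pos and (x == 0).any():
            return x


class TestTwoPartLRT:
    def test_identical_groups_give_zero(self):
        a = np.array([0, 0, 1.2, 3.4, 0, 2.2])
        res = two_part_lrt(a, a.copy())
        assert res.stat == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_all_zero_vs_all_positive_closed_form(self):
        # only the detection component is defined; at p-hat 0, 1 and pooled
        # 0.5 the binomial LRT is -2 * 20 * ln(0.5)
        res = two_part_lrt(np.zeros(10), np.full(10, 2.0))
        assert res.df == 1
        assert res.stat == pytest.approx(-2 * 20 * np.log(0.5), rel=1e-12)
        assert res.p == pytest.approx(1.3978e-7, rel=1e-4)

    def test_matches_numeric_optimization_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            a = zero_inflated(rng, int(rng.integers(5, 51)))
            b = zero_inflated(rng, int(rng.integers(5, 51)))
            mine = two_part_lrt(a, b).stat
            assert mine == pytest.approx(oracle_two_part_stat(a, b), abs=1e-6)

    def test_continuous_component_skipped_below_two_positives(self):
        a = np.array([0.0, 0, 0, 0, 1.5])   # one positive value
        b = np.array([2.0, 2.5, 0, 3.0, 0])
        assert two_part_lrt(a, b).df == 1

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a, b = zero_inflated(rng, 20), zero_inflated(rng, 15)
            r1, r2 = two_part_lrt(a, b), two_part_lrt(b, a)
            assert r1.stat == pytest.approx(r2.stat, rel=1e-12)
            assert r1.p == pytest.approx(r2.p, rel=1e-12)

    def test_table_matches_scalar_calls(self):
        rng = np.random.default_rng(11)
        A = np.vstack([zero_inflated(rng, 30, min_pos=0) for _ in range(20)])
        B = np.vstack([zero_inflated(rng, 25, min_pos=0) for _ in range(20)])
        tbl = two_part_lrt_table(A, B)
        for i in range(20):
            res = two_part_lrt(A[i], B[i])
            assert tbl["stat"].iloc[i] == pytest.approx(res.stat, rel=1e-12, abs=1e-12)
            assert tbl["df"].iloc[i] == res.df

    def test_degenerate_zero_variance(self):
        # constant but different positives: infinite continuous evidence,
        # p floored above zero
        res = two_part_lrt(np.array([1.0, 1.0, 1.0]), np.array([2.0, 2.0, 2.0]))
        assert np.isinf(res.stat) and res.p > 0 and res.p_floored
        # constant and identical positives: contribution 0
        res2 = two_part_lrt(np.array([1.0, 1.0, 0.0]), np.array([1.0, 1.0]))
        assert np.isfinite(res2.stat)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            two_part_lrt(np.array([]), np.array([1.0, 2.0]))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=2, max_size=40),
           st.lists(st.floats(0, 10, allow_nan=False), min_size=2, max_size=40))
    def test_stat_nonnegative_p_valid(self, a, b):
        res = two_part_lrt(np.array(a), np.array(b))
        assert res.stat >= -1e-9
        assert 0.0 < res.p <= 1.0


class TestBH:
    def test_hand_computed_example(self):
        p = np.array([0.005, 0.009, 0.05, 0.1, 0.9])
        expected = [0.0225, 0.0225, 0.25 / 3, 0.125, 0.9]
        assert bh_adjust(p) == pytest.approx(expected)

    def test_monotone_and_at_least_p(self):
        rng = np.random.default_rng(5)
        p = rng.random(100)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestFindMarkers:
    def test_planted_markers_recovered(self, small_norm, small_experiment):
        _, _, meta, truth = small_experiment
        tbl = find_markers(small_norm, meta, "cluster00")
        up = set(tbl.loc[tbl["logfc"] > 0, "gene"])
        planted = set(truth.markers["cluster00"])
        assert len(up & planted) / len(planted) >= 0.8

    def test_prefilter_boundary_excludes_frac_029(self):
        # 100 cells per group; 29 vs 30 detected cells straddle the 30% gate
        n_cells = 200
        vals = np.zeros((2, n_cells))
        vals[0, :29] = 1.0
        vals[0, 100:129] = 5.0   # frac 0.29 in both groups, big logfc
        vals[1, :30] = 1.0
        vals[1, 100:130] = 5.0   # frac 0.30: tested
        n = make_norm(vals)
        meta = make_meta(n.cells, "sham", cluster=["A"] * 100 + ["B"] * 100)
        tbl = find_markers(n, meta, "B", alpha=0.999)
        assert "g0" not in set(tbl["gene"])
        assert "g1" in set(tbl["gene"])

    def test_unknown_cluster(self, small_norm, small_experiment):
        _, _, meta, _ = small_experiment
        with pytest.raises(ValueError, match="unknown cluster"):
            find_markers(small_norm, meta, "nope")

    def test_no_gene_passes_prefilter_gives_empty_table(self):
        n = make_norm(np.zeros((3, 8)))
        meta = make_meta(n.cells, "sham", cluster=["A"] * 4 + ["B"] * 4)
        tbl = find_markers(n, meta, "A")
        assert len(tbl) == 0
        assert list(tbl.columns) == de.DEG_COLUMNS


class TestFindDEGs:
    def test_restricted_deg_detected_only_in_its_cluster(self, small_norm,
                                                         small_experiment):
        _, _, meta, truth = small_experiment
        mine = truth.degs[truth.degs["clusters"].map(lambda t: t == ("cluster00",))]
        found = set(find_degs(small_norm, meta, "cluster00", "tbi", "sham")["gene"])
        other = set(find_degs(small_norm, meta, "cluster01", "tbi", "sham")["gene"])
        assert len(found & set(mine["gene"])) >= 3  # of 4 planted
        assert not (other & set(mine["gene"]))

    def test_relaxed_p_mode_contains_fdr_mode(self, small_norm, small_experiment):
        _, _, meta, _ = small_experiment
        strict = find_degs(small_norm, meta, "cluster00", "tbi", "sham")
        relaxed = find_degs(small_norm, meta, "cluster00", "tbi", "sham", p_cut=0.01)
        if len(strict) and strict["p"].max() <= 0.01:
            assert set(strict["gene"]) <= set(relaxed["gene"])

    def test_same_condition_is_error(self, small_norm, small_experiment):
        _, _, meta, _ = small_experiment
        with pytest.raises(ValueError, match="must differ"):
            find_degs(small_norm, meta, "cluster00", "tbi", "tbi")


class TestBulkComparison:
    def test_null_data_empty_sets_p1(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(0, 1, size=(30, 120))
        vals[rng.random(vals.shape) < 0.4] = 0
        n = make_norm(vals)
        meta = make_meta(n.cells, ["sham"] * 60 + ["tbi"] * 60,
                         animal=[f"a{i // 20}" for i in range(120)])
        out = bulk_vs_sc_comparison(n, meta, {}, "tbi", "sham")
        assert out["shared"] == [] and out["sc_only"] == []
        assert out["fisher_p"] == pytest.approx(1.0)

    def test_requires_two_animals_per_condition(self):
        n = make_norm(np.ones((5, 40)))
        meta = make_meta(n.cells, ["sham"] * 20 + ["tbi"] * 20,
                         animal=["a1"] * 20 + ["a2"] * 20)
        with pytest.raises(ValueError, match="2 animals"):
            bulk_vs_sc_comparison(n, meta, {}, "tbi", "sham")


class TestReversal:
    def _tables(self):
        dis = pd.DataFrame({"gene": ["up1", "up2", "ns"],
                            "logfc": [1.0, 0.8, 0.5],
                            "p": [0.001, 0.01, 0.4]})
        trt = pd.DataFrame({"gene": ["up1", "up2", "other"],
                            "logfc": [-0.5, 0.7, -1.0],
                            "p": [0.01, 0.02, 0.001]})
        return dis, trt

    def test_sign_logic(self):
        dis, trt = self._tables()
        res = reversal_analysis(dis, trt)
        assert res.overlap == ["up1", "up2"]
        assert res.reversed_genes == ["up1"]      # opposite signs
        assert res.concordant == ["up2"]          # same sign
        assert 0 < res.fisher_p <= 1

    def test_disjoint_significant_sets(self):
        dis = pd.DataFrame({"gene": ["a"], "logfc": [1.0], "p": [0.01]})
        trt = pd.DataFrame({"gene": ["b"], "logfc": [1.0], "p": [0.01]})
        res = reversal_analysis(dis, trt)
        assert res.overlap == [] and res.reversed_genes == []

    def test_missing_columns_error(self):
        dis, trt = self._tables()
        with pytest.raises(ValueError, match="missing columns"):
            reversal_analysis(dis.drop(columns=["logfc"]), trt)
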