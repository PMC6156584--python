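from math import comb

import numpy as np
import pandas as pd
import pytest

from dropcell.annotate import (GeneSetCollection, annotate_clusters, bonferroni,
                               enrich, fisher_overlap, proportion_test,
                               read_gmt, write_gmt)

from oracles import oracle_hypergeom_sf


def genes(prefix, n):
    return [f"{prefix}{i}" for i in range(n)]


class TestFisherOverlap:
    def test_query_equals_reference_equals_universe(self):
        u = genes("g", 10)
        res = fisher_overlap(u, u, u)
        assert res.overlap == 10
        assert res.p == pytest.approx(1.0)

    def test_perfect_overlap_closed_form(self):
        u = genes("g", 100)
        q = u[:10]
        res = fisher_overlap(q, q, u)
        assert res.p == pytest.approx(1.0 / comb(100, 10), rel=1e-12)

    def test_matches_enumeration_on_small_tables(self):
        # spot-check grid here; the exhaustive sweep runs in the acceptance suite
        u = genes("g", 12)
        for nq in (0, 3, 7, 12):
            for nr in (0, 4, 12):
                for k in range(0, min(nq, nr) + 1):
                    q = u[:k] + genes("onlyq", nq - k)
                    r = u[:k] + genes("onlyr", nr - k)
                    universe = set(u) | set(q) | set(r)
                    extra = 12 - len(universe)
                    universe |= set(genes("pad", max(extra, 0)))
                    res = fisher_overlap(q, r, universe)
                    exp = oracle_hypergeom_sf(k, len(universe), nr, nq)
                    assert res.p == pytest.approx(exp, abs=1e-12)

    def test_out_of_universe_genes_dropped(self):
        res = fisher_overlap(["a", "zzz"], ["a"], ["a", "b", "c"])
        assert res.query_size == 1 and res.overlap == 1

    def test_empty_universe_error(self):
        with pytest.raises(ValueError, match="universe"):
            fisher_overlap(["a"], ["a"], [])


class TestAnnotateClusters:
    @pytest.fixture
    def refs(self):
        return GeneSetCollection({"astro": genes("a", 10), "micro": genes("m", 10)})

    def test_exact_match_wins(self, refs):
        universe = genes("a", 10) + genes("m", 10) + genes("x", 80)
        adj, assigned = annotate_clusters({"c1": genes("a", 10)}, refs, universe)
        assert assigned["c1"] == "astro"
        assert adj.loc["c1", "astro"] < adj.loc["c1", "micro"]

    def test_disjoint_markers_are_unknown(self, refs):
        universe = genes("a", 10) + genes("m", 10) + genes("x", 80)
        _, assigned = annotate_clusters({"c1": genes("x", 10)}, refs, universe)
        assert assigned["c1"] == "unknown"

    def test_gene_and_cluster_order_invariance(self, refs):
        universe = genes("a", 10) + genes("m", 10) + genes("x", 80)
        markers = {"c1": genes("a", 8), "c2": genes("m", 8)}
        rev = {"c2": list(reversed(markers["c2"])), "c1": list(reversed(markers["c1"]))}
        adj1, as1 = annotate_clusters(markers, refs, universe)
        adj2, as2 = annotate_clusters(rev, refs, universe)
        assert as1 == as2
        pd.testing.assert_frame_equal(adj1, adj2)

    def test_noisy_references_still_recover_identities(self):
        # generator round trip: markers discovered from synthetic clusters,
        # matched against references with 30% of members replaced by decoys
        from dropcell import de, io_qc
        from dropcell.syndata import (SynthConfig, generate_experiment,
                                      generate_reference_sets)
        correct = total = 0
        for seed in range(20):
            cfg = SynthConfig(n_clusters=5, n_genes=300, cells_per_animal=60,
                              markers_per_cluster=12, marker_frac_in=0.8,
                              marker_frac_out=0.1, degs_per_cluster=0,
                              seed=seed)
            m, meta, truth = generate_experiment(cfg)
            norm = io_qc.normalize(m)
            refs = generate_reference_sets(truth, noise=0.3, seed=seed,
                                           universe=list(m.genes))
            markers = {cl: de.find_markers(norm, meta, cl)
                       for cl in cfg.cluster_labels()
                       if (meta["cluster"] == cl).sum() >= 2}
            universe = set(np.asarray(m.genes)[(m.values > 0).any(axis=1)])
            _, assigned = annotate_clusters(markers, refs, universe)
            correct += sum(assigned[cl] == f"ref_{cl}" for cl in assigned)
            total += len(assigned)
        assert correct / total >= 0.8  # >= 4/5 clusters on average

    def test_empty_references_error(self):
        with pytest.raises(ValueError, match="reference"):
            annotate_clusters({"c1": ["a"]}, GeneSetCollection({}), ["a"])

    def test_bonferroni_is_min_of_one_and_scaled(self):
        p = np.array([0.001, 0.3, 0.9])
        assert bonferroni(p, 4) == pytest.approx([0.004, 1.0, 1.0])


class TestEnrich:
    def test_source_pathway_ranks_first(self):
        universe = genes("g", 200)
        paths = GeneSetCollection({"hit": universe[:20], "other": universe[50:70]})
        out = enrich(universe[:10], paths, universe)
        assert out.iloc[0]["set"] == "hit"
        assert out.iloc[0]["adj_p"] < 0.05

    def test_pathway_outside_universe_skipped(self):
        universe = genes("g", 50)
        paths = GeneSetCollection({"ok": universe[:5], "ghost": ["not", "here"]})
        out = enrich(universe[:5], paths, universe)
        assert list(out["set"]) == ["ok"]


class TestProportionTest:
    def _meta(self, rows):
        recs = []
        for cluster, cond, n in rows:
            recs += [{"condition": cond, "animal": "a", "cluster": cluster}] * n
        return pd.DataFrame(recs, index=[f"c{i}" for i in range(len(recs))])

    def test_identical_composition_p_one(self):
        meta = self._meta([("K", "sham", 50), ("K", "tbi", 50),
                           ("L", "sham", 50), ("L", "tbi", 50)])
        out = proportion_test(meta)
        assert np.allclose(out["p"], 1.0)

    def test_lopsided_cluster_significant(self):
        # a 100-cell cluster split 89 tbi / 11 sham against an even background
        meta = self._meta([("epen", "tbi", 89), ("epen", "sham", 11),
                           ("K", "tbi", 450), ("K", "sham", 450)])
        out = proportion_test(meta).set_index("cluster")
        assert out.loc["epen", "p"] < 0.05
        assert out.attrs["caveat"]

    def test_single_cluster_no_contrast(self):
        meta = self._meta([("K", "sham", 30), ("K", "tbi", 40)])
        out = proportion_test(meta)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_condition_without_cells_error(self):
        meta = self._meta([("K", "sham", 10)])
        with pytest.raises(ValueError):
            proportion_test(meta, "sham", "tbi")


class TestGMT:
    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection({"s1": ["a", "b", "c"], "s2": ["d", "e"]},
                                 {"s1": "first", "s2": "second"})
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert back.sets == coll.sets
        assert back.descriptions == coll.descriptions

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("name_only\tdesc\n")
        with pytest.raises(ValueError, match="GMT"):
            read_gmt(path)
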