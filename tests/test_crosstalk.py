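import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dropcell.crosstalk import (build_networks, interaction_score,
                                permutation_null, score_pairs,
                                select_source_genes, trisynaptic_benchmark)
from dropcell.syndata import CrosstalkBlock, generate_animal_summaries


def summary(vals, genes=None, animals=None):
    vals = np.asarray(vals, dtype=float)
    genes = genes or [f"g{i}" for i in range(vals.shape[0])]
    animals = animals or [f"a{i}" for i in range(vals.shape[1])]
    return pd.DataFrame(vals, index=genes, columns=animals)


class TestSelectSources:
    def test_intersection_and_exclusion(self):
        markers = {"A": ["p1", "x1"], "B": ["x2"]}
        out = select_source_genes(markers, ["p1", "p9"])
        assert out == {"A": ["p1"]}  # B has no secreted marker: not a source

    def test_accepts_deg_tables(self):
        markers = {"A": pd.DataFrame({"gene": ["p1", "x"]})}
        assert select_source_genes(markers, ["p1"]) == {"A": ["p1"]}

    def test_empty_list_error(self):
        with pytest.raises(ValueError):
            select_source_genes({"A": ["x"]}, [])


class TestInteractionScore:
    def test_hand_instance_matches_pearson(self):
        src = summary([[1.0, 2.0, 4.0, 3.0]], genes=["pep"])
        tgt = summary([[2.0, 3.0, 5.0, 3.5], [9.0, 1.0, 4.0, 4.0]])
        records, S = interaction_score(src, tgt, "pep")
        expected = 0.0
        for i in range(2):
            r, p = stats.pearsonr(src.loc["pep"], tgt.iloc[i])
            assert records["r"].iloc[i] == pytest.approx(r, abs=1e-10)
            assert records["p"].iloc[i] == pytest.approx(p, abs=1e-10)
            expected += -np.log10(p)
        assert S == pytest.approx(expected, abs=1e-10)

    def test_proportional_target_dominates(self):
        pep = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        rng = np.random.default_rng(0)
        tgt = summary(np.vstack([2 * pep, rng.normal(size=(5, 6))]))
        records, S = interaction_score(summary([pep], genes=["pep"]), tgt, "pep")
        assert records["neglog10_p"].iloc[0] == records["neglog10_p"].max()
        assert records["neglog10_p"].iloc[0] >= 0.5 * S

    def test_constant_targets_excluded(self):
        src = summary([[1.0, 2.0, 3.0, 4.0]], genes=["pep"])
        tgt = summary(np.ones((3, 4)))
        records, S = interaction_score(src, tgt, "pep")
        assert S == 0.0
        assert records["p"].isna().all()

    def test_constant_peptide_error(self):
        src = summary([[2.0, 2.0, 2.0, 2.0]], genes=["pep"])
        with pytest.raises(ValueError, match="constant"):
            interaction_score(src, summary(np.eye(4)), "pep")

    def test_too_few_shared_animals_error(self):
        src = summary([[1.0, 2.0]], genes=["pep"], animals=["a", "b"])
        tgt = summary([[1.0, 2.0]], animals=["a", "b"])
        with pytest.raises(ValueError, match="shared animals"):
            interaction_score(src, tgt, "pep")

    def test_additive_and_order_invariant(self):
        rng = np.random.default_rng(1)
        src = summary([rng.normal(size=8)], genes=["pep"])
        tgt = summary(rng.normal(size=(10, 8)))
        _, S_all = interaction_score(src, tgt, "pep")
        _, S_a = interaction_score(src, tgt.iloc[:4], "pep")
        _, S_b = interaction_score(src, tgt.iloc[4:], "pep")
        _, S_shuf = interaction_score(src, tgt.sample(frac=1, random_state=0), "pep")
        assert S_all == pytest.approx(S_a + S_b, rel=1e-12)
        assert S_all == pytest.approx(S_shuf, rel=1e-12)

    def test_joint_animal_relabeling_leaves_score_unchanged(self):
        rng = np.random.default_rng(2)
        src = summary([rng.normal(size=8)], genes=["pep"])
        tgt = summary(rng.normal(size=(6, 8)))
        perm = rng.permutation(8)
        _, S1 = interaction_score(src, tgt, "pep")
        _, S2 = interaction_score(src.iloc[:, perm], tgt.iloc[:, perm], "pep")
        assert S1 == pytest.approx(S2, rel=1e-12)


class TestPermutationNull:
    def test_seed_determinism_and_floor(self):
        rng = np.random.default_rng(3)
        src = summary([rng.normal(size=10)], genes=["pep"])
        tgt = summary(rng.normal(size=(8, 10)))
        r1 = permutation_null(src, tgt, "pep", n_perm=200, seed=5)
        r2 = permutation_null(src, tgt, "pep", n_perm=200, seed=5)
        assert r1.p_empirical == r2.p_empirical
        assert r1.p_empirical >= 1.0 / 201

    def test_planted_block_attains_min_p(self):
        block = CrosstalkBlock("A", "g0000", "B",
                               tuple(f"g{i:04d}" for i in range(10, 30)), 0.9)
        summ = generate_animal_summaries(["A", "B"], 60, 12, [block], seed=4)
        res = permutation_null(summ["A"], summ["B"], "g0000", n_perm=200, seed=4)
        assert res.p_empirical == pytest.approx(1.0 / 201)

    def test_invalid_n_perm(self):
        src = summary([[1.0, 2.0, 3.0]], genes=["pep"])
        with pytest.raises(ValueError):
            permutation_null(src, src, "pep", n_perm=0)


class TestNetworks:
    def _scores(self, ps):
        return pd.DataFrame({
            "source_cluster": ["A", "B"], "peptide_gene": ["p1", "p2"],
            "target_cluster": ["B", "A"], "score": [5.0, 1.0],
            "n_target_genes": [10, 10], "n_excluded": [0, 0],
            "n_animals": [6, 6], "p_empirical": ps,
        })

    def test_identical_scores_give_empty_differential(self):
        nets = build_networks({"sham": self._scores([0.01, 0.5]),
                               "tbi": self._scores([0.01, 0.5])})
        assert len(nets["differential"]) == 0
        assert len(nets["edges"]["sham"]) == 1

    def test_alpha_one_keeps_all_edges(self):
        nets = build_networks({"sham": self._scores([0.9, 0.99]),
                               "tbi": self._scores([0.9, 0.99])}, alpha=1.01)
        assert len(nets["edges"]["sham"]) == 2

    def test_gained_edge_reported(self):
        nets = build_networks({"sham": self._scores([0.5, 0.5]),
                               "tbi": self._scores([0.01, 0.5])})
        diff = nets["differential"]
        assert len(diff) == 1 and diff["significant_in"].iloc[0] == "tbi"

    def test_mismatched_inventories_error(self):
        other = self._scores([0.1, 0.1])
        other.loc[0, "target_cluster"] = "Z"
        with pytest.raises(ValueError, match="inventories"):
            build_networks({"sham": self._scores([0.1, 0.1]), "tbi": other})


class TestTrisynaptic:
    def test_self_pairs_present_and_square(self):
        blocks = [CrosstalkBlock("DG", "g0000", "CA3",
                                 tuple(f"g{i:04d}" for i in range(5, 20)), 0.9)]
        summ = generate_animal_summaries(["DG", "CA3", "CA1"], 40, 10,
                                         blocks, seed=6)
        mat = trisynaptic_benchmark(summ, ["g0000"], n_perm=100, seed=6)
        assert mat.shape == (3, 3)
        assert not mat.isna().any().any()          # self-pairs computed too
        assert mat.loc["DG", "CA3"] == mat.min().min()

    def test_requires_three_clusters(self):
        summ = generate_animal_summaries(["A", "B"], 10, 6, seed=0)
        with pytest.raises(ValueError, match="3 clusters"):
            trisynaptic_benchmark(summ, ["g0000"], n_perm=10)
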