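import numpy as np
import pandas as pd
import pytest

from dropcell import io_qc
from dropcell.syndata import (CrosstalkBlock, SynthConfig,
                              generate_animal_summaries, generate_experiment,
                              generate_reference_sets)


def small_cfg(**kw):
    base = dict(n_clusters=3, n_genes=120, cells_per_animal=60,
                markers_per_cluster=8, degs_per_cluster=3, seed=0)
    base.update(kw)
    return SynthConfig(**base)


class TestGenerateExperiment:
    def test_config_echo(self):
        m, meta, truth = generate_experiment(
            small_cfg(n_clusters=3, cells_per_animal=100, animals_per_condition=3))
        assert m.n_cells == 600
        assert meta["animal"].nunique() == 6
        assert set(meta["condition"]) == {"sham", "tbi"}
        assert set(truth.markers) == set(meta["cluster"].unique())

    def test_seeded_determinism(self):
        m1, meta1, _ = generate_experiment(small_cfg(seed=11))
        m2, meta2, _ = generate_experiment(small_cfg(seed=11))
        assert np.array_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(meta1, meta2)

    def test_different_seeds_differ(self):
        m1, _, _ = generate_experiment(small_cfg(seed=1))
        m2, _, _ = generate_experiment(small_cfg(seed=2))
        assert not np.array_equal(m1.values, m2.values)

    def test_planted_marker_elevated_in_its_cluster(self):
        # Monte-Carlo over seeds: mean log-normalized expression of a planted
        # marker inside its cluster exceeds the outside mean
        wins = 0
        for seed in range(20):
            m, meta, truth = generate_experiment(small_cfg(seed=seed,
                                                           marker_logfc=1.0))
            norm = io_qc.normalize(m)
            cl = "cluster00"
            gene = truth.markers[cl][0]
            gi = m.genes.get_loc(gene)
            in_cl = (meta["cluster"] == cl).to_numpy()
            wins += norm.values[gi, in_cl].mean() > norm.values[gi, ~in_cl].mean()
        assert wins >= 19

    def test_overdispersed_relative_to_poisson(self):
        m, _, _ = generate_experiment(small_cfg(dispersion=0.5, seed=3))
        mu = m.values.mean(axis=1)
        var = m.values.var(axis=1)
        expressed = mu > 0.05
        assert (var[expressed] / mu[expressed]).mean() > 1.0

    def test_deg_restricted_to_cluster_shifts_only_there(self):
        m, meta, truth = generate_experiment(small_cfg(seed=5, cells_per_animal=200))
        norm = io_qc.normalize(m)
        row = truth.degs[truth.degs["logfc"] > 0].iloc[0]
        gi = m.genes.get_loc(row["gene"])
        target_cl = row["clusters"][0]
        other_cl = next(c for c in truth.markers if c != target_cl)
        def cond_diff(cl):
            sel = (meta["cluster"] == cl).to_numpy()
            tbi = sel & (meta["condition"] == "tbi").to_numpy()
            sham = sel & (meta["condition"] == "sham").to_numpy()
            return norm.values[gi, tbi].mean() - norm.values[gi, sham].mean()
        assert cond_diff(target_cl) > 0.3
        assert abs(cond_diff(other_cl)) < cond_diff(target_cl)

    def test_invalid_abundances_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_experiment(small_cfg(cluster_abundances=(0.5, 0.4, 0.2)))

    def test_gene_budget_too_small(self):
        with pytest.raises(ValueError, match="gene budget"):
            generate_experiment(small_cfg(n_genes=10))

    def test_crosstalk_peptide_becomes_source_marker(self):
        block = CrosstalkBlock("cluster00", "g0000", "cluster01",
                               ("g0001", "g0002"), 0.8)
        m, meta, truth = generate_experiment(small_cfg(crosstalk_blocks=(block,),
                                                       n_genes=200))
        assert "g0000" in truth.markers["cluster00"]
        assert truth.crosstalk == (block,)


class TestReferenceSets:
    @pytest.fixture
    def truth(self):
        _, _, truth = generate_experiment(small_cfg(seed=8))
        return truth

    def test_noise_zero_reproduces_markers(self, truth):
        refs = generate_reference_sets(truth, noise=0.0,
                                       universe=[f"g{i:04d}" for i in range(120)])
        for cl, genes in truth.markers.items():
            assert sorted(refs.sets[f"ref_{cl}"]) == sorted(genes)

    def test_noise_half_replaces_exact_count(self, truth):
        universe = [f"g{i:04d}" for i in range(120)]
        refs = generate_reference_sets(truth, noise=0.5, seed=1, universe=universe)
        for cl, genes in truth.markers.items():
            got = refs.sets[f"ref_{cl}"]
            kept = set(got) & set(genes)
            assert len(got) == len(genes)
            assert len(kept) == len(genes) - round(0.5 * len(genes))

    def test_gmt_round_trip(self, truth, tmp_path):
        from dropcell.annotate import read_gmt, write_gmt
        refs = generate_reference_sets(truth, noise=0.0,
                                       universe=[f"g{i:04d}" for i in range(120)])
        write_gmt(refs, tmp_path / "r.gmt")
        assert read_gmt(tmp_path / "r.gmt").sets == refs.sets


class TestAnimalSummaries:
    def test_planted_correlation_close_to_r(self):
        block = CrosstalkBlock("A", "g0000", "B", ("g0001",), 0.9)
        summ = generate_animal_summaries(["A", "B"], 5, 4000, [block], seed=0)
        r = np.corrcoef(summ["A"].loc["g0000"], summ["B"].loc["g0001"])[0, 1]
        assert r == pytest.approx(0.9, abs=0.02)

    def test_unplanted_genes_uncorrelated(self):
        summ = generate_animal_summaries(["A", "B"], 5, 4000, seed=1)
        r = np.corrcoef(summ["A"].loc["g0002"], summ["B"].loc["g0003"])[0, 1]
        assert abs(r) < 0.05

    def test_unknown_cluster_in_block_error(self):
        block = CrosstalkBlock("A", "g0000", "Z", ("g0001",), 0.5)
        with pytest.raises(ValueError, match="unknown cluster"):
            generate_animal_summaries(["A", "B"], 5, 10, [block])
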