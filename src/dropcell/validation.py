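"""Simulation studies validating the statistical machinery end to end.

Each function runs a self-contained seeded study on synthetic data with
planted truth and returns the measured operating characteristics: type-I
error of the two-part LRT under a null generator, sensitivity/FDR of marker
recovery, calibration and power of the transcriptome-shift permutation test,
recovery of planted crosstalk couplings, masking of rare-cluster DEGs in
pseudobulk, and knee-gate behavior on bimodal spot-count mixtures. The test
suite asserts on these numbers and the acceptance script reports them; both
call this module so the quantities are always recomputed from scratch.

Problem sizes default to desk scale (single CPU, minutes); see each
docstring for the defaults used.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import de, io_qc, ish, shift
from .crosstalk import score_pairs, trisynaptic_benchmark
from .syndata import (CrosstalkBlock, SynthConfig, generate_animal_summaries,
                      generate_experiment, generate_spot_counts)

__all__ = [
    "lrt_type1_error",
    "marker_recovery",
    "deg_masking",
    "shift_calibration",
    "shift_power",
    "crosstalk_recovery",
    "trisynaptic_recovery",
    "knee_separation",
]


def _zero_inflated(rng, shape, zero_rate=0.4, mu=0.5, sigma=0.5):
    x = rng.lognormal(mu, sigma, size=shape)
    x[rng.random(shape) < zero_rate] = 0.0
    return x


def lrt_type1_error(n_per_group: int = 200, n_reps: int = 2000,
                    alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical type-I error of the two-part LRT at ``alpha``.

    Both groups are drawn from one zero-inflated lognormal; each replicate is
    one gene row of a vectorized test.
    """
    rng = np.random.default_rng(seed)
    a = _zero_inflated(rng, (n_reps, n_per_group))
    b = _zero_inflated(rng, (n_reps, n_per_group))
    tbl = de.two_part_lrt_table(a, b)
    return float((tbl["p"] < alpha).mean())


def _marker_config(seed: int) -> SynthConfig:
    # the marker-recovery regime: detection 0.8 inside vs 0.1 outside the
    # cluster, no condition DEGs planted
    return SynthConfig(n_clusters=5, n_genes=500, cells_per_animal=150,
                       markers_per_cluster=20, marker_frac_in=0.8,
                       marker_frac_out=0.1, degs_per_cluster=0, seed=seed)


def marker_recovery(n_seeds: int = 20, alpha: float = 0.05,
                    seed: int = 0) -> dict:
    """Sensitivity and observed FDR of marker discovery on planted markers.

    A cluster's markers are its enriched genes, so discovery is evaluated on
    the up-regulated rows of each marker table against the planted registry.
    """
    tp = fp = fn = 0
    for s in range(n_seeds):
        cfg = _marker_config(seed + s)
        m, meta, truth = generate_experiment(cfg)
        norm = io_qc.normalize(m)
        for cl in cfg.cluster_labels():
            tbl = de.find_markers(norm, meta, cl, alpha=alpha)
            up = set(tbl.loc[tbl["logfc"] > 0, "gene"])
            planted = set(truth.markers[cl])
            tp += len(up & planted)
            fp += len(up - planted)
            fn += len(planted - up)
    return {"sensitivity": tp / (tp + fn), "fdr": fp / max(tp + fp, 1),
            "n": n_seeds}


def deg_masking(n_seeds: int = 20, rare_abundance: float = 0.02,
                seed: int = 0) -> dict:
    """Detection and pseudobulk masking of DEGs planted in a rare cluster.

    One cluster holds ``rare_abundance`` of the cells; its planted DEGs should
    appear in that cluster's DEG table and be absent from the in-silico bulk
    table at identical thresholds.
    """
    n_bg = 4
    ab = (rare_abundance,) + ((1.0 - rare_abundance) / n_bg,) * n_bg
    detected = masked = total = 0
    for s in range(n_seeds):
        cfg = SynthConfig(n_clusters=5, cluster_abundances=ab, n_genes=400,
                          cells_per_animal=800, markers_per_cluster=10,
                          degs_per_cluster=4, seed=seed + s)
        m, meta, truth = generate_experiment(cfg)
        norm = io_qc.normalize(m)
        rare = cfg.cluster_labels()[0]
        planted = set(truth.degs.loc[
            truth.degs["clusters"].map(lambda t: t == (rare,)), "gene"])
        tbl = de.find_degs(norm, meta, rare, "tbi", "sham")
        cmp = de.bulk_vs_sc_comparison(norm, meta, {rare: tbl}, "tbi", "sham")
        found = set(tbl["gene"]) & planted
        detected += len(found)
        masked += len(found & set(cmp["sc_only"]))
        total += len(planted)
    return {"detected_rate": detected / total, "masked_rate": masked / total,
            "n": n_seeds}


def _null_cluster(rng, n_genes, n_cells_per_cond):
    vals = _zero_inflated(rng, (n_genes, 2 * n_cells_per_cond),
                          zero_rate=0.5, mu=0.0, sigma=1.0)
    genes = pd.Index([f"g{i}" for i in range(n_genes)])
    cells = pd.Index([f"c{i}" for i in range(2 * n_cells_per_cond)])
    norm = io_qc.NormMatrix(vals, genes, cells)
    meta = pd.DataFrame({"condition": ["sham"] * n_cells_per_cond
                         + ["tbi"] * n_cells_per_cond,
                         "animal": "a1", "cluster": "K"}, index=cells)
    return norm, meta


def shift_calibration(n_reps: int = 200, n_perm: int = 200, n_genes: int = 100,
                      n_cells_per_cond: int = 40, seed: int = 0) -> dict:
    """KS uniformity of shift-test empirical p under a label-exchangeable null."""
    rng = np.random.default_rng(seed)
    ps = []
    for _ in range(n_reps):
        norm, meta = _null_cluster(rng, n_genes, n_cells_per_cond)
        res = shift.transcriptome_shift(norm, meta, "K", "sham", "tbi",
                                        n_perm=n_perm, rng=rng)
        ps.append(res.p_empirical)
    ks = stats.kstest(ps, "uniform")
    return {"ks_p": float(ks.pvalue), "mean_p": float(np.mean(ps)), "n": n_reps}


def shift_power(n_seeds: int = 50, n_perm: int = 1000, shift_size: float = 0.5,
                n_shifted_genes: int = 50, n_genes: int = 200,
                n_cells_per_cond: int = 100, p_target: float = 0.01,
                seed: int = 0) -> dict:
    """Power of the shift test against a planted mean shift.

    ``shift_size`` ln-units are added to ``n_shifted_genes`` genes of one
    condition; reports the fraction of seeds reaching ``p <= p_target``.
    """
    hits = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 1000 + s)
        norm, meta = _null_cluster(rng, n_genes, n_cells_per_cond)
        vals = norm.values
        vals[:n_shifted_genes, (meta["condition"] == "tbi").to_numpy()] += shift_size
        res = shift.transcriptome_shift(norm, meta, "K", "sham", "tbi",
                                        n_perm=n_perm, rng=rng)
        hits += res.p_empirical <= p_target
    return {"power": hits / n_seeds, "n": n_seeds}


def crosstalk_recovery(n_seeds: int = 50, n_perm: int = 1000,
                       n_animals: int = 12, n_target_genes: int = 30,
                       r: float = 0.9, seed: int = 0) -> dict:
    """Recovery of a planted peptide -> target-gene-block coupling.

    Three cell types; a block of ``n_target_genes`` genes in cluster B is
    coupled at correlation ``r`` to cluster A's peptide. Success: the planted
    (A, B) pair attains the smallest empirical p among all 9 source x target
    pairs. Null-pair calibration is measured on pairs targeting cluster C,
    which carries no planted structure (pairs targeting B share its
    correlated block, which the independent-shuffle null counts as signal).
    """
    wins = 0
    null_ps = []
    targets = tuple(f"g{i:04d}" for i in range(10, 10 + n_target_genes))
    for s in range(n_seeds):
        block = CrosstalkBlock("A", "g0000", "B", targets, r)
        summ = generate_animal_summaries(["A", "B", "C"], 100, n_animals,
                                         [block], seed=seed + s)
        sources = {"A": ["g0000"], "B": ["g0050"], "C": ["g0070"]}
        tbl = score_pairs(summ, sources, n_perm=n_perm, seed=seed + s)
        key = (tbl["source_cluster"] == "A") & (tbl["target_cluster"] == "B")
        wins += tbl.loc[key, "p_empirical"].iloc[0] <= tbl["p_empirical"].min()
        null_ps.extend(tbl.loc[tbl["target_cluster"] == "C", "p_empirical"])
    ks = stats.kstest(null_ps, "uniform")
    return {"recovery_rate": wins / n_seeds, "null_ks_p": float(ks.pvalue),
            "n": n_seeds}


def trisynaptic_recovery(n_seeds: int = 25, n_perm: int = 500,
                         n_animals: int = 10, r: float = 0.9,
                         seed: int = 0) -> dict:
    """Recovery of the DG<->CA3 / CA3->CA1 coupling topology.

    Plants the three couplings among DG, CA3 and CA1 via glutamate-secretion
    source genes; success when exactly those three cells rank first in the
    3x3 matrix ordered by empirical p with the observed score as tie-break.
    """
    glut = ["g0000", "g0001", "g0002"]
    planted = {("DG", "CA3"), ("CA3", "DG"), ("CA3", "CA1")}
    wins = 0
    for s in range(n_seeds):
        blocks = [
            CrosstalkBlock("DG", "g0000", "CA3",
                           tuple(f"g{i:04d}" for i in range(10, 40)), r),
            CrosstalkBlock("CA3", "g0001", "DG",
                           tuple(f"g{i:04d}" for i in range(40, 70)), r),
            CrosstalkBlock("CA3", "g0001", "CA1",
                           tuple(f"g{i:04d}" for i in range(40, 70)), r),
        ]
        summ = generate_animal_summaries(["DG", "CA3", "CA1"], 100, n_animals,
                                         blocks, seed=seed + s)
        mat = trisynaptic_benchmark(summ, glut, n_perm=n_perm, seed=seed + s)
        # rank by empirical p, then by observed score: several cells can
        # saturate the permutation grid's minimum p (see the benchmark's
        # tie-break note), and the planted couplings carry far larger scores
        flat = pd.DataFrame({"p": mat.stack(), "s": mat.attrs["scores"].stack()})
        flat = flat.sort_values(["p", "s"], ascending=[True, False])
        wins += set(flat.index[:3]) == planted
    return {"recovery_rate": wins / n_seeds, "n": n_seeds}


def knee_separation(n_seeds: int = 100, mode_low: float = 2.0,
                    mode_high: float = 30.0, n_cells: int = 300,
                    seed: int = 0) -> dict:
    """Fraction of bimodal spot-count fixtures whose knee falls between modes."""
    ok = 0
    for s in range(n_seeds):
        spots = generate_spot_counts(n_cells, marker_low=mode_low,
                                     marker_high=mode_high, seed=seed + s)
        thr = ish.knee_threshold(spots["marker_count"])
        ok += mode_low < thr <= mode_high
    return {"separation_rate": ok / n_seeds, "n": n_seeds}
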