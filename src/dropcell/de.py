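"""Two-part ("bimodal") likelihood-ratio test and analyses built on it.

Single-cell expression is zero-heavy: a gene is either undetected (value 0)
or detected with some continuous log-normalized magnitude. The two-part LRT
combines

* a binomial LRT on the detection rate (fraction of cells with value > 0),
  1 df, and
* an equal-variance Gaussian LRT on the magnitudes among detected cells,
  1 df, computed only when both groups have at least two detected cells.

The two log-likelihoods add (the components are variation-independent), the
statistic is referred to a chi-square with df = number of computed
components. Fold changes are differences of group means of the ln-scale
normalized values with zeros included, so ``logfc`` is in natural-log units.

Marker discovery contrasts one cluster against all remaining cells; DEG
discovery contrasts two conditions within a cluster. Both apply the standard
prefilters before testing: detection fraction >= ``min_frac`` in at least one
group and |logfc| >= ``min_logfc``; Benjamini-Hochberg is applied across the
tested genes of each contrast.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

from .io_qc import NormMatrix, validate_meta

log = logging.getLogger(__name__)

__all__ = [
    "TwoPartStat",
    "ReversalResult",
    "two_part_lrt",
    "two_part_lrt_table",
    "bh_adjust",
    "find_markers",
    "find_degs",
    "bulk_vs_sc_comparison",
    "reversal_analysis",
]

_P_FLOOR = float(np.finfo(float).tiny)

DEG_COLUMNS = ["gene", "frac_a", "frac_b", "mean_a", "mean_b",
               "logfc", "stat", "df", "p", "fdr"]


@dataclass
class TwoPartStat:
    stat: float
    df: int
    p: float
    p_floored: bool = False


@dataclass
class ReversalResult:
    """Overlap of a disease and a treatment DE signature."""

    overlap: list
    reversed_genes: list
    concordant: list
    fisher_p: float
    universe_size: int


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _binom_ll(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    return xlogy(k, p) + xlogy(n - k, 1.0 - p)


def two_part_lrt_table(a: np.ndarray, b: np.ndarray):
    """Vectorized two-part LRT over rows (genes).

    Parameters
    ----------
    a, b : arrays of shape (n_genes, n_cells_group) with non-negative values;
        0 encodes "not detected".

    Returns
    -------
    DataFrame with columns frac_a, frac_b, mean_a, mean_b, logfc, stat, df, p.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError(f"each group needs >= 2 observations (got {na}, {nb})")

    ka = (a > 0).sum(axis=1).astype(float)
    kb = (b > 0).sum(axis=1).astype(float)
    # binomial component on detection rates
    p_a, p_b = ka / na, kb / nb
    p_pool = (ka + kb) / (na + nb)
    stat_d = 2.0 * (_binom_ll(ka, na, p_a) + _binom_ll(kb, nb, p_b)
                    - _binom_ll(ka + kb, na + nb, p_pool))
    stat_d = np.maximum(stat_d, 0.0)

    # Gaussian component on positive values (zeros contribute nothing to sums)
    sa, sb = a.sum(axis=1), b.sum(axis=1)
    ssa, ssb = (a ** 2).sum(axis=1), (b ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ssd_a = ssa - np.where(ka > 0, sa ** 2 / np.maximum(ka, 1), 0.0)
        ssd_b = ssb - np.where(kb > 0, sb ** 2 / np.maximum(kb, 1), 0.0)
        npos = ka + kb
        ssd_alt = ssd_a + ssd_b
        ssd_null = (ssa + ssb) - np.where(npos > 0, (sa + sb) ** 2 / np.maximum(npos, 1), 0.0)
    has_cont = (ka >= 2) & (kb >= 2)
    ssd_alt = np.maximum(ssd_alt, 0.0)
    ssd_null = np.maximum(ssd_null, ssd_alt)  # null is nested: never smaller
    stat_c = np.zeros_like(stat_d)
    tiny = 1e-300
    pos_var = has_cont & (ssd_alt > tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat_c[pos_var] = npos[pos_var] * np.log(ssd_null[pos_var] / ssd_alt[pos_var])
    # degenerate: zero within-group variance; infinite evidence unless the
    # group means coincide too (then the statistic is 0)
    degen = has_cont & (ssd_alt <= tiny)
    stat_c[degen & (ssd_null > 1e-12)] = np.inf
    stat_c = np.maximum(stat_c, 0.0)

    stat = stat_d + stat_c
    df = 1 + has_cont.astype(int)
    p = stats.chi2.sf(stat, df)
    floored = p < _P_FLOOR
    p = np.maximum(p, _P_FLOOR)

    mean_a = sa / na
    mean_b = sb / nb
    return pd.DataFrame({
        "frac_a": p_a, "frac_b": p_b,
        "mean_a": mean_a, "mean_b": mean_b,
        "logfc": mean_a - mean_b,
        "stat": stat, "df": df, "p": p, "p_floored": floored,
    })


def two_part_lrt(a, b) -> TwoPartStat:
    """Two-part LRT for a single gene; see :func:`two_part_lrt_table`."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("two_part_lrt: a group is empty")
    row = two_part_lrt_table(a[None, :], b[None, :]).iloc[0]
    return TwoPartStat(float(row["stat"]), int(row["df"]), float(row["p"]),
                       bool(row["p_floored"]))


# ---------------------------------------------------------------------------
# marker / DEG discovery


def _contrast_table(n: NormMatrix, mask_a: np.ndarray, mask_b: np.ndarray,
                    min_frac: float, min_logfc: float, alpha: float,
                    p_cut: float | None) -> pd.DataFrame:
    X = n.values
    A, B = X[:, mask_a], X[:, mask_b]
    na, nb = A.shape[1], B.shape[1]
    if na < 2 or nb < 2:
        raise ValueError(f"each group needs >= 2 cells (got {na}, {nb})")
    frac_a = (A > 0).mean(axis=1)
    frac_b = (B > 0).mean(axis=1)
    logfc = A.mean(axis=1) - B.mean(axis=1)
    tested = (np.maximum(frac_a, frac_b) >= min_frac) & (np.abs(logfc) >= min_logfc)
    if not tested.any():
        log.warning("no genes pass the prefilter (min_frac=%.2f, min_logfc=%.2f)",
                    min_frac, min_logfc)
        return pd.DataFrame(columns=DEG_COLUMNS)
    res = two_part_lrt_table(A[tested], B[tested])
    res.insert(0, "gene", np.asarray(n.genes)[tested])
    res["fdr"] = bh_adjust(res["p"].to_numpy())
    if p_cut is not None:
        res = res[res["p"] < p_cut]
    else:
        res = res[res["fdr"] < alpha]
    res = res.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)
    res = res[DEG_COLUMNS]
    res.attrs.update({"min_frac": min_frac, "min_logfc": min_logfc,
                      "alpha": alpha, "p_cut": p_cut,
                      "n_a": na, "n_b": nb})
    return res


def find_markers(n: NormMatrix, meta: pd.DataFrame, cluster: str,
                 min_frac: float = 0.3, min_logfc: float = 0.25,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Markers of ``cluster`` vs all remaining cells (FDR < alpha)."""
    validate_meta(meta)
    meta = meta.loc[n.cells]
    clusters = meta["cluster"].to_numpy()
    if cluster not in set(clusters):
        raise ValueError(f"unknown cluster {cluster!r}")
    in_c = clusters == cluster
    return _contrast_table(n, in_c, ~in_c, min_frac, min_logfc, alpha, None)


def find_degs(n: NormMatrix, meta: pd.DataFrame, cluster: str,
              cond_a: str, cond_b: str,
              min_frac: float = 0.3, min_logfc: float = 0.25,
              alpha: float = 0.05, p_cut: float | None = None) -> pd.DataFrame:
    """Condition DEGs within a cluster.

    By default returns genes at FDR < ``alpha``; with ``p_cut`` set (e.g. 0.01
    for rare cell types) returns genes at unadjusted p < ``p_cut`` instead.
    """
    if cond_a == cond_b:
        raise ValueError("cond_a and cond_b must differ")
    validate_meta(meta)
    meta = meta.loc[n.cells]
    if cluster is not None:
        sel = (meta["cluster"] == cluster).to_numpy()
        if not sel.any():
            raise ValueError(f"unknown cluster {cluster!r}")
    else:
        sel = np.ones(len(meta), dtype=bool)
    cond = meta["condition"].to_numpy()
    mask_a = sel & (cond == cond_a)
    mask_b = sel & (cond == cond_b)
    if not mask_a.any() or not mask_b.any():
        raise ValueError(f"a condition has no cells in cluster {cluster!r}")
    return _contrast_table(n, mask_a, mask_b, min_frac, min_logfc, alpha, p_cut)


# ---------------------------------------------------------------------------
# single-cell vs in-silico bulk


def _fisher_overlap_p(set_a: set, set_b: set, universe: set) -> float:
    a = set_a & universe
    b = set_b & universe
    k = len(a & b)
    if not universe:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, len(universe), len(b), len(a)))


def bulk_vs_sc_comparison(n: NormMatrix, meta: pd.DataFrame,
                          sc_degs: dict, cond_a: str, cond_b: str,
                          min_frac: float = 0.3, min_logfc: float = 0.25,
                          alpha: float = 0.05) -> dict:
    """Compare cluster-level DEGs against an in-silico bulk analysis.

    Bulk profiles are per-animal means over all cells (pseudobulk); the same
    two-part test and thresholds are applied with animals as observations.
    Returns the bulk DEG table, the single-cell DEGs captured in bulk
    (``shared``), those masked (``sc_only``), and a Fisher overlap p against
    the detected-gene universe.
    """
    from .io_qc import pseudobulk  # local import to avoid cycle at module load

    validate_meta(meta)
    meta = meta.loc[n.cells]
    pb = pseudobulk(n, meta)  # genes x animals
    animal_cond = meta.drop_duplicates("animal").set_index("animal")["condition"]
    a_animals = [a for a in pb.columns if animal_cond[a] == cond_a]
    b_animals = [a for a in pb.columns if animal_cond[a] == cond_b]
    if len(a_animals) < 2 or len(b_animals) < 2:
        raise ValueError("need >= 2 animals per condition for the bulk comparison")
    bulk_n = NormMatrix(pb.to_numpy(), pb.index, pd.Index(pb.columns),
                        provenance={"kind": "pseudobulk"})
    mask_a = np.isin(pb.columns, a_animals)
    bulk_table = _contrast_table(bulk_n, mask_a, ~mask_a,
                                 min_frac, min_logfc, alpha, None)
    bulk_genes = set(bulk_table["gene"])
    sc_union = set()
    for tbl in sc_degs.values():
        sc_union |= set(tbl["gene"])
    universe = set(np.asarray(n.genes)[(n.values > 0).any(axis=1)])
    shared = sorted(sc_union & bulk_genes)
    sc_only = sorted(sc_union - bulk_genes)
    return {
        "bulk_table": bulk_table,
        "shared": shared,
        "sc_only": sc_only,
        "fisher_p": _fisher_overlap_p(sc_union, bulk_genes, universe),
        "universe_size": len(universe),
    }


# ---------------------------------------------------------------------------
# treatment reversal


def reversal_analysis(de_disease: pd.DataFrame, de_treatment: pd.DataFrame,
                      p_cut: float = 0.05, universe=None) -> ReversalResult:
    """Classify treatment effects against a disease DE signature.

    ``overlap`` = genes with p < ``p_cut`` in both tables; ``reversed`` =
    overlap genes whose logfc signs are opposite; the Fisher p tests the
    overlap against ``universe`` (default: union of genes in both tables).
    """
    for name, tbl in (("de_disease", de_disease), ("de_treatment", de_treatment)):
        missing = {"gene", "logfc", "p"} - set(tbl.columns)
        if missing:
            raise ValueError(f"{name} is missing columns {sorted(missing)}")
    sig_d = de_disease[de_disease["p"] < p_cut].set_index("gene")["logfc"]
    sig_t = de_treatment[de_treatment["p"] < p_cut].set_index("gene")["logfc"]
    overlap = sorted(set(sig_d.index) & set(sig_t.index))
    rev = [g for g in overlap if np.sign(sig_d[g]) * np.sign(sig_t[g]) < 0]
    conc = [g for g in overlap if g not in set(rev)]
    if universe is None:
        universe = set(de_disease["gene"]) | set(de_treatment["gene"])
    universe = set(universe)
    p = _fisher_overlap_p(set(sig_d.index), set(sig_t.index), universe)
    return ReversalResult(overlap, rev, conc, p, len(universe))
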