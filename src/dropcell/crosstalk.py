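"""Secreted-peptide cell-cell gene co-expression ("crosstalk") scoring.

A cell type whose markers include genes encoding secreted peptides is a
candidate *source*; any cell type is a candidate *target*. Expression is
first summarized to the animal level within each cell type (genes x animals
mean matrices). For a given (source, peptide, target) triple, the peptide's
animal-level profile is Pearson-correlated with every target gene's profile;
the interaction score is

    S = sum over target genes of -log10 p(correlation),

with each term capped (default 15) to keep S finite. Significance comes from
a permutation null in which every target gene's animal-level values are
shuffled independently while the peptide profile stays fixed; the empirical p
is add-one smoothed. Setting the secreted list to glutamate-secretion genes
turns the same machinery into the trisynaptic-circuit benchmark, where the
known DG<->CA3 and CA3->CA1 couplings serve as positive controls
(self-pairs are computed and reported, not suppressed).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

log = logging.getLogger(__name__)

__all__ = [
    "InteractionScore",
    "select_source_genes",
    "interaction_score",
    "permutation_null",
    "score_pairs",
    "build_networks",
    "trisynaptic_benchmark",
]

DEFAULT_NEGLOG10_CAP = 15.0


@dataclass
class InteractionScore:
    source_cluster: str
    peptide_gene: str
    target_cluster: str
    score: float
    n_target_genes: int
    n_excluded: int
    n_animals: int
    p_empirical: float = float("nan")
    seed: int | None = None


def select_source_genes(markers: dict, secreted_list) -> dict:
    """Per-cluster intersection of marker genes with a secreted-peptide list.

    Clusters with an empty intersection are omitted (they cannot be sources).
    """
    secreted = set(secreted_list)
    if not secreted:
        raise ValueError("secreted list is empty")
    out = {}
    for cluster, tbl in markers.items():
        genes = list(tbl["gene"]) if isinstance(tbl, pd.DataFrame) else list(tbl)
        pep = sorted(set(genes) & secreted)
        if pep:
            out[cluster] = pep
    return out


def _corr_pvals(pep: np.ndarray, T: np.ndarray):
    """Pearson r and two-sided t-test p of each row of T against ``pep``.

    Rows with zero variance (or if pep is constant) give NaN.
    """
    n = pep.size
    pc = pep - pep.mean()
    Tc = T - T.mean(axis=1, keepdims=True)
    denom = np.sqrt((pc @ pc) * (Tc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Tc @ pc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = r * r * (n - 2) / (1.0 - r * r)
    t2 = np.where(np.isclose(np.abs(r), 1.0), np.inf, t2)
    # two-sided p from the t distribution; betainc form handles t = inf
    p = np.where(np.isinf(t2), 0.0,
                 special.betainc((n - 2) / 2.0, 0.5, (n - 2) / ((n - 2) + t2)))
    p = np.where(np.isnan(r), np.nan, p)
    return r, p


def _shared_summaries(source_summary: pd.DataFrame, target_summary: pd.DataFrame,
                      peptide: str, min_animals: int = 3):
    shared = source_summary.columns.intersection(target_summary.columns)
    if len(shared) < min_animals:
        raise ValueError(f"only {len(shared)} shared animals; need >= {min_animals}")
    if peptide not in source_summary.index:
        raise ValueError(f"peptide {peptide!r} absent from the source summary")
    pep = source_summary.loc[peptide, shared].to_numpy(dtype=float)
    if np.allclose(pep, pep[0]):
        raise ValueError(
            f"peptide {peptide!r} is constant across animals; its correlations are "
            "undefined — check the animal-level summary or pick another peptide"
        )
    T = target_summary.loc[:, shared].to_numpy(dtype=float)
    return pep, T, list(shared)


def _score_from_pvals(p: np.ndarray, cap: float) -> tuple[float, int, int]:
    defined = ~np.isnan(p)
    with np.errstate(divide="ignore"):
        terms = np.minimum(-np.log10(np.maximum(p[defined], 10.0 ** (-cap - 1))), cap)
    return float(terms.sum()), int(defined.sum()), int((~defined).sum())


def interaction_score(source_summary: pd.DataFrame, target_summary: pd.DataFrame,
                      peptide: str, cap: float = DEFAULT_NEGLOG10_CAP,
                      min_animals: int = 3):
    """Correlation records and summed -log10 p score for one peptide.

    Returns ``(records, S)``: a DataFrame with one row per target gene
    (r, p, -log10 p term; NaN rows are excluded from S and counted), and the
    interaction score S.
    """
    pep, T, shared = _shared_summaries(source_summary, target_summary, peptide,
                                       min_animals)
    r, p = _corr_pvals(pep, T)
    S, n_def, n_exc = _score_from_pvals(p, cap)
    if n_exc:
        log.info("interaction_score: %d target genes with undefined correlation "
                 "excluded", n_exc)
    with np.errstate(divide="ignore"):
        term = np.where(np.isnan(p), np.nan,
                        np.minimum(-np.log10(np.maximum(p, 10.0 ** (-cap - 1))), cap))
    records = pd.DataFrame({"target_gene": target_summary.index, "r": r, "p": p,
                            "neglog10_p": term})
    records.attrs.update({"peptide": peptide, "n_animals": len(shared),
                          "n_excluded": n_exc, "score": S})
    return records, S


def permutation_null(source_summary: pd.DataFrame, target_summary: pd.DataFrame,
                     peptide: str, n_perm: int = 1000,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None,
                     cap: float = DEFAULT_NEGLOG10_CAP,
                     min_animals: int = 3) -> InteractionScore:
    """Empirical p for the interaction score of one (peptide, target) pair.

    Each permutation shuffles every target gene's animal-level values
    independently (the peptide stays fixed) and recomputes S.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pep, T, shared = _shared_summaries(source_summary, target_summary, peptide,
                                       min_animals)
    _, p_obs = _corr_pvals(pep, T)
    s_obs, n_def, n_exc = _score_from_pvals(p_obs, cap)
    if rng is None:
        rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        T_perm = rng.permuted(T, axis=1)  # independent shuffle per target gene
        _, p_null = _corr_pvals(pep, T_perm)
        s_null, _, _ = _score_from_pvals(p_null, cap)
        if s_null >= s_obs:
            exceed += 1
    p_emp = (1.0 + exceed) / (1.0 + n_perm)
    return InteractionScore(
        source_cluster="", peptide_gene=peptide, target_cluster="",
        score=s_obs, n_target_genes=n_def, n_excluded=n_exc,
        n_animals=len(shared), p_empirical=p_emp, seed=seed,
    )


def score_pairs(summaries: dict, sources: dict, n_perm: int = 1000,
                seed: int | None = None, cap: float = DEFAULT_NEGLOG10_CAP,
                min_animals: int = 3, exclude_peptide_from_target: bool = True
                ) -> pd.DataFrame:
    """All (source cluster, peptide, target cluster) interaction scores.

    ``summaries`` maps cluster -> genes x animals summary; ``sources`` maps
    cluster -> peptide genes. Self-pairs are included. Returns one row per
    triple with score and empirical p.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for src in sorted(sources):
        for pep in sources[src]:
            for tgt in sorted(summaries):
                tgt_summary = summaries[tgt]
                if exclude_peptide_from_target and pep in tgt_summary.index:
                    tgt_summary = tgt_summary.drop(index=pep)
                res = permutation_null(summaries[src], tgt_summary, pep,
                                       n_perm=n_perm, rng=rng, cap=cap,
                                       min_animals=min_animals)
                rows.append({"source_cluster": src, "peptide_gene": pep,
                             "target_cluster": tgt, "score": res.score,
                             "n_target_genes": res.n_target_genes,
                             "n_excluded": res.n_excluded,
                             "n_animals": res.n_animals,
                             "p_empirical": res.p_empirical})
    return pd.DataFrame(rows, columns=["source_cluster", "peptide_gene",
                                       "target_cluster", "score",
                                       "n_target_genes", "n_excluded",
                                       "n_animals", "p_empirical"])


def build_networks(scores_by_condition: dict, alpha: float = 0.05) -> dict:
    """Significant edges per condition plus the differential (gained/lost) set.

    ``scores_by_condition`` maps condition -> score table from
    :func:`score_pairs` computed on the same cluster inventory.
    """
    inventories = {
        cond: (frozenset(t["source_cluster"]) | frozenset(t["target_cluster"]))
        for cond, t in scores_by_condition.items()
    }
    if len(set(inventories.values())) > 1:
        raise ValueError(f"cluster inventories differ between conditions: {inventories}")
    edges = {}
    keys = ["source_cluster", "peptide_gene", "target_cluster"]
    for cond, tbl in scores_by_condition.items():
        e = tbl[tbl["p_empirical"] < alpha].reset_index(drop=True)
        edges[cond] = e
    conds = list(scores_by_condition)
    diff_rows = []
    if len(conds) == 2:
        sets = {c: set(map(tuple, edges[c][keys].to_numpy())) for c in conds}
        for c, other in (conds, conds[::-1]):
            for triple in sorted(sets[c] - sets[other]):
                diff_rows.append({**dict(zip(keys, triple)), "significant_in": c})
    differential = pd.DataFrame(diff_rows, columns=keys + ["significant_in"])
    return {"edges": edges, "differential": differential, "alpha": alpha}


def trisynaptic_benchmark(summaries: dict, glutamate_genes, n_perm: int = 1000,
                          seed: int | None = None,
                          cap: float = DEFAULT_NEGLOG10_CAP,
                          min_animals: int = 3) -> pd.DataFrame:
    """Directed source x target empirical-p matrix using glutamate-secretion
    genes as the source peptides.

    The combined statistic per (source, target) cell sums S over the source's
    glutamate genes with animal-level variance; peptides constant across
    animals are skipped with a log message. Self-pairs are computed.
    """
    if len(summaries) < 3:
        raise ValueError("need summaries for >= 3 clusters")
    glut = list(glutamate_genes)
    clusters = sorted(summaries)
    rng = np.random.default_rng(seed)
    mat = pd.DataFrame(index=clusters, columns=clusters, dtype=float)
    smat = pd.DataFrame(index=clusters, columns=clusters, dtype=float)
    for src in clusters:
        peptides = [g for g in glut if g in summaries[src].index]
        usable = []
        for pep in peptides:
            v = summaries[src].loc[pep].to_numpy(dtype=float)
            if np.allclose(v, v[0]):
                log.info("trisynaptic_benchmark: peptide %s constant in %s; skipped",
                         pep, src)
            else:
                usable.append(pep)
        if not usable:
            raise ValueError(f"no usable glutamate-secretion genes in cluster {src!r}")
        for tgt in clusters:
            tgt_summary = summaries[tgt].drop(index=[p for p in usable
                                                     if p in summaries[tgt].index])
            shared = summaries[src].columns.intersection(tgt_summary.columns)
            if len(shared) < min_animals:
                raise ValueError(f"only {len(shared)} shared animals for {src}->{tgt}")
            peps = summaries[src].loc[usable, shared].to_numpy(dtype=float)
            T = tgt_summary.loc[:, shared].to_numpy(dtype=float)
            s_obs = sum(_score_from_pvals(_corr_pvals(pep, T)[1], cap)[0]
                        for pep in peps)
            exceed = 0
            for _ in range(n_perm):
                T_perm = rng.permuted(T, axis=1)
                s_null = sum(_score_from_pvals(_corr_pvals(pep, T_perm)[1], cap)[0]
                             for pep in peps)
                if s_null >= s_obs:
                    exceed += 1
            mat.loc[src, tgt] = (1.0 + exceed) / (1.0 + n_perm)
            smat.loc[src, tgt] = s_obs
    mat.index.name = "source"
    mat.columns.name = "target"
    smat.index.name = "source"
    smat.columns.name = "target"
    # observed scores break ties on the permutation grid (the shuffle null is
    # anticonservative when target genes are mutually correlated, so several
    # cells can saturate the minimum attainable p)
    mat.attrs["scores"] = smat
    return mat
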