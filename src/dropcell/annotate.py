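"""Cluster identity annotation and gene-set over-representation.

Clusters are labeled by Fisher-exact (hypergeometric) overlap of their
derived marker genes with reference marker sets, Bonferroni-corrected across
all (cluster x reference) tests; clusters whose markers overlap no reference
significantly are labeled ``"unknown"``. General pathway enrichment uses the
same one-sided test with Benjamini-Hochberg across sets. Cluster-proportion
shifts between conditions use a two-sided Fisher test per cluster — with the
caveat that droplet capture rates confound proportion estimates, so caution
is needed in the interpretation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "fisher_overlap",
    "annotate_clusters",
    "enrich",
    "proportion_test",
    "bonferroni",
]

PROPORTION_CAVEAT = (
    "Droplet capture rates differ between samples and a shift in one cluster "
    "moves all relative proportions; caution is needed in the interpretation."
)


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict = field(default_factory=dict)          # name -> list of genes
    descriptions: dict = field(default_factory=dict)  # name -> str
    universe: set | None = None

    def __post_init__(self) -> None:
        self.sets = {name: list(dict.fromkeys(genes))  # dedupe, keep order
                     for name, genes in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class EnrichmentResult:
    name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    odds_ratio: float
    p: float
    adj_p: float = float("nan")
    adjust_method: str = ""
    overlapping_genes: list = field(default_factory=list)


def read_gmt(path) -> GeneSetCollection:
    sets, desc = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need name, "
                                 f"description and >=1 member")
            sets[parts[0]] = [g for g in parts[2:] if g]
            desc[parts[0]] = parts[1]
    return GeneSetCollection(sets, desc)


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in coll:
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def _restrict(genes, universe: set, what: str) -> set:
    genes = set(genes)
    kept = genes & universe
    dropped = len(genes) - len(kept)
    if dropped:
        log.warning("fisher_overlap: dropped %d %s genes outside the universe",
                    dropped, what)
    return kept


def fisher_overlap(query, reference, universe) -> EnrichmentResult:
    """One-sided (enrichment) hypergeometric p for |query ∩ reference|."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    q = _restrict(query, universe, "query")
    r = _restrict(reference, universe, "reference")
    inter = sorted(q & r)
    k, nq, nr, N = len(inter), len(q), len(r), len(universe)
    p = float(stats.hypergeom.sf(k - 1, N, nr, nq))
    # odds ratio of the 2x2 table (inf when a margin is exhausted)
    b, c, d = nq - k, nr - k, N - nq - nr + k
    odds = (k * d) / (b * c) if b * c > 0 else float("inf") if k * d > 0 else float("nan")
    return EnrichmentResult(name="", overlap=k, set_size=nr, query_size=nq,
                            universe_size=N, odds_ratio=odds, p=min(p, 1.0),
                            overlapping_genes=inter)


def bonferroni(p, m: int) -> np.ndarray:
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)


def _as_gene_list(markers):
    if isinstance(markers, pd.DataFrame):
        if "logfc" in markers.columns:
            # a cluster's identity markers are its enriched genes; depleted
            # genes mostly echo other clusters' markers
            return list(markers.loc[markers["logfc"] > 0, "gene"])
        return list(markers["gene"])
    return list(markers)


def annotate_clusters(markers: dict, references: GeneSetCollection,
                      universe, alpha: float = 0.05):
    """Assign a reference identity to each cluster by marker overlap.

    Returns ``(adj_p_matrix, assignments)`` where the matrix is clusters x
    references of Bonferroni-adjusted p values and assignments maps cluster ->
    best reference name (or ``"unknown"``). Ties on adjusted p break by larger
    overlap, then lexicographic reference name.
    """
    if len(references) == 0:
        raise ValueError("empty reference collection")
    if not markers:
        raise ValueError("no marker tables supplied")
    clusters = sorted(markers)
    refs = sorted(references.sets)
    m = len(clusters) * len(refs)
    raw = pd.DataFrame(index=clusters, columns=refs, dtype=float)
    counts = pd.DataFrame(index=clusters, columns=refs, dtype=float)
    for cl in clusters:
        q = _as_gene_list(markers[cl])
        for ref in refs:
            res = fisher_overlap(q, references.sets[ref], universe)
            raw.loc[cl, ref] = res.p
            counts.loc[cl, ref] = res.overlap
    adj = raw.apply(lambda col: bonferroni(col, m))
    assignments = {}
    for cl in clusters:
        order = sorted(refs, key=lambda r: (adj.loc[cl, r], -counts.loc[cl, r], r))
        best = order[0]
        assignments[cl] = best if adj.loc[cl, best] < alpha else "unknown"
    return adj, assignments


def enrich(query, pathways: GeneSetCollection, universe) -> pd.DataFrame:
    """Over-representation of ``query`` in each pathway, BH-adjusted, ranked by p."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    rows = []
    for name, genes in pathways:
        if not set(genes) & universe:
            log.warning("enrich: pathway %s has no genes in the universe; skipped", name)
            continue
        res = fisher_overlap(query, genes, universe)
        rows.append({"set": name, "overlap": res.overlap, "set_size": res.set_size,
                     "query_size": res.query_size, "universe_size": res.universe_size,
                     "odds_ratio": res.odds_ratio, "p": res.p,
                     "genes": ",".join(res.overlapping_genes)})
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "query_size",
                                      "universe_size", "odds_ratio", "p", "genes"])
    if len(out):
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    else:
        out["adj_p"] = []
    return out


def proportion_test(meta: pd.DataFrame, cond_a: str | None = None,
                    cond_b: str | None = None) -> pd.DataFrame:
    """Per-cluster 2x2 Fisher test of composition between two conditions.

    Two-sided (shifts can go either way), BH across clusters. The returned
    table carries a caveat string in ``attrs['caveat']``.
    """
    conds = pd.unique(meta["condition"])
    if cond_a is None or cond_b is None:
        if len(conds) != 2:
            raise ValueError("specify cond_a/cond_b when more than two conditions exist")
        cond_a, cond_b = conds
    n_a = int((meta["condition"] == cond_a).sum())
    n_b = int((meta["condition"] == cond_b).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("a condition has zero cells")
    rows = []
    for cl in sorted(pd.unique(meta["cluster"])):
        in_a = int(((meta["cluster"] == cl) & (meta["condition"] == cond_a)).sum())
        in_b = int(((meta["cluster"] == cl) & (meta["condition"] == cond_b)).sum())
        table = [[in_a, n_a - in_a], [in_b, n_b - in_b]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"cluster": cl, f"n_{cond_a}": in_a, f"n_{cond_b}": in_b,
                     "prop_a": in_a / n_a, "prop_b": in_b / n_b,
                     "prop_diff": in_a / n_a - in_b / n_b, "p": float(p)})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out.attrs["caveat"] = PROPORTION_CAVEAT
    out.attrs["conditions"] = (cond_a, cond_b)
    return out
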