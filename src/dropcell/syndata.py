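"""Synthetic Drop-seq-like experiments with planted ground truth.

The generator emulates a two-condition (sham vs tbi) droplet scRNA-seq design
with a few animals per condition, unequal cluster abundances, cluster-specific
marker genes, condition DEGs that may be restricted to a subset of clusters,
per-animal depth variation, and animal-level source-peptide -> target-gene
correlation blocks across cell types.

Count model
-----------
UMI counts are gamma-Poisson (negative binomial) around a per-gene baseline
mean with multiplicative effects:

* marker genes are elevated in their own cluster, either by a fold
  ``exp(marker_logfc)`` or by solving the count model for target detection
  fractions (``marker_frac_in`` / ``marker_frac_out``);
* DEGs are shifted between conditions (alternating signs) only in their
  restricted clusters;
* every animal carries a global lognormal depth factor (it cancels under
  per-cell UMI normalization, mimicking capture-depth variation);
* crosstalk blocks share a per-animal latent factor between the source
  peptide (in the source cluster) and the target genes (in the target
  cluster), inducing animal-level correlation of strength ``r``.

On top of the NB draw, each entry is independently zeroed with probability a
decreasing logistic function of the underlying mean (dropout).

All randomness flows from one root seed through named
``numpy.random.SeedSequence`` child streams (baseline, assignment, animal,
crosstalk, counts, dropout), so identical config + seed gives bit-identical
output.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .annotate import GeneSetCollection
from .io_qc import CountMatrix

__all__ = [
    "CrosstalkBlock",
    "SynthConfig",
    "GroundTruth",
    "generate_experiment",
    "generate_reference_sets",
    "generate_spot_counts",
    "generate_animal_summaries",
]

_STREAMS = ("baseline", "assign", "animal", "crosstalk", "counts", "dropout")


def _split_rngs(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass(frozen=True)
class CrosstalkBlock:
    source_cluster: str
    peptide_gene: str
    target_cluster: str
    target_genes: tuple
    r: float


def _default_abundances(k: int) -> np.ndarray:
    # geometric decay from ~40% to ~1%, like real droplet cluster inventories
    w = np.geomspace(40.0, 1.0, k)
    return w / w.sum()


@dataclass
class SynthConfig:
    n_clusters: int = 12
    cluster_abundances: tuple | None = None
    cluster_names: tuple | None = None
    n_genes: int = 2000
    cells_per_animal: int = 500
    animals_per_condition: int = 3
    conditions: tuple = ("sham", "tbi")
    baseline_mean: float = 0.2
    baseline_sigma: float = 1.0
    dispersion: float = 0.3
    dropout_logit_slope: float = 1.0
    dropout_midpoint: float = 0.0
    markers_per_cluster: int = 20
    marker_logfc: float = 1.0
    marker_frac_in: float | None = None
    marker_frac_out: float | None = None
    degs_per_cluster: int = 10
    deg_logfc: float = 1.5
    deg_cluster_restriction: dict = field(default_factory=dict)
    crosstalk_blocks: tuple = ()
    crosstalk_tau: float = 0.5
    animal_sigma: float = 0.15
    seed: int = 0

    def cluster_labels(self) -> list:
        if self.cluster_names is not None:
            return list(self.cluster_names)
        return [f"cluster{i:02d}" for i in range(self.n_clusters)]

    def abundances(self) -> np.ndarray:
        if self.cluster_abundances is None:
            return _default_abundances(self.n_clusters)
        return np.asarray(self.cluster_abundances, dtype=float)

    def validate(self) -> None:
        for name in ("n_clusters", "n_genes", "cells_per_animal",
                     "animals_per_condition", "markers_per_cluster"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if self.degs_per_cluster < 0:
            raise ValueError("degs_per_cluster must be >= 0")
        w = self.abundances()
        if len(w) != self.n_clusters:
            raise ValueError(f"{len(w)} abundance weights for {self.n_clusters} clusters")
        if (w <= 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("cluster_abundances must be strictly positive and sum to 1")
        if self.cluster_names is not None and len(self.cluster_names) != self.n_clusters:
            raise ValueError("cluster_names length must equal n_clusters")
        for f in ("baseline_mean",):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.dispersion < 0 or self.animal_sigma < 0:
            raise ValueError("dispersion and animal_sigma must be >= 0")
        planted = self.n_clusters * (self.markers_per_cluster + self.degs_per_cluster)
        if planted > self.n_genes:
            raise ValueError(
                f"gene budget too small: {planted} planted genes > n_genes={self.n_genes}"
            )
        labels = set(self.cluster_labels())
        for g, cls in self.deg_cluster_restriction.items():
            unknown = set(cls) - labels
            if unknown:
                raise ValueError(f"deg_cluster_restriction for {g!r} names unknown "
                                 f"clusters {sorted(unknown)}")
        for b in self.crosstalk_blocks:
            if b.source_cluster not in labels or b.target_cluster not in labels:
                raise ValueError(f"crosstalk block references unknown cluster: {b}")
            if not (0.0 <= abs(b.r) <= 1.0):
                raise ValueError(f"crosstalk r must be in [-1, 1]: {b}")


@dataclass
class GroundTruth:
    cell_clusters: pd.Series                 # barcode -> cluster
    markers: dict                            # cluster -> list of genes
    degs: pd.DataFrame                       # gene, clusters, logfc
    crosstalk: tuple                         # CrosstalkBlocks as planted

    def validate_against(self, m: CountMatrix) -> None:
        genes = set(m.genes)
        for cl, gs in self.markers.items():
            missing = set(gs) - genes
            if missing:
                raise ValueError(f"marker registry for {cl} names absent genes {missing}")
        missing = set(self.degs["gene"]) - genes
        if missing:
            raise ValueError(f"DEG registry names absent genes {missing}")


# ---------------------------------------------------------------------------
# count-model helpers


def _keep_prob(mu: np.ndarray, slope: float, midpoint: float) -> np.ndarray:
    # probability an entry survives dropout; increasing in the underlying mean
    return 1.0 / (1.0 + np.exp(-slope * (np.log1p(mu) - midpoint)))


def _detection_prob(mu: float, dispersion: float, slope: float, midpoint: float) -> float:
    if dispersion > 0:
        p_zero_nb = (1.0 + mu * dispersion) ** (-1.0 / dispersion)
    else:
        p_zero_nb = np.exp(-mu)
    return float((1.0 - p_zero_nb) * _keep_prob(np.asarray(mu), slope, midpoint))


def _solve_mean_for_fraction(frac: float, dispersion: float, slope: float,
                             midpoint: float) -> float:
    """Invert the count model: NB mean whose detection probability is ``frac``."""
    if not 0.0 < frac < 1.0:
        raise ValueError("target detection fraction must be in (0, 1)")
    f = lambda mu: _detection_prob(mu, dispersion, slope, midpoint) - frac
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError(f"detection fraction {frac} unreachable under this model")
    return float(brentq(f, 1e-9, hi))


# ---------------------------------------------------------------------------
# main generator


def generate_experiment(config: SynthConfig):
    """Simulate an experiment; returns ``(CountMatrix, meta, GroundTruth)``."""
    config.validate()
    rngs = _split_rngs(config.seed)
    labels = config.cluster_labels()
    genes = pd.Index([f"g{i:04d}" for i in range(config.n_genes)])

    for g in config.deg_cluster_restriction:
        if g not in set(genes):
            raise ValueError(f"deg_cluster_restriction names unknown gene {g!r}")

    # -- planted gene assignment (disjoint marker/DEG pools)
    perm = rngs["assign"].permutation(config.n_genes)
    cursor = 0
    markers = {}
    for cl in labels:
        markers[cl] = sorted(genes[perm[cursor:cursor + config.markers_per_cluster]])
        cursor += config.markers_per_cluster
    deg_rows = []
    for cl in labels:
        for j in range(config.degs_per_cluster):
            gene = genes[perm[cursor]]
            cursor += 1
            restricted = tuple(config.deg_cluster_restriction.get(gene, (cl,)))
            sign = 1.0 if j % 2 == 0 else -1.0
            deg_rows.append({"gene": gene, "clusters": restricted,
                             "logfc": sign * config.deg_logfc})
    degs = pd.DataFrame(deg_rows, columns=["gene", "clusters", "logfc"])

    assigned = set(degs["gene"]) | set().union(*markers.values())
    for b in config.crosstalk_blocks:
        if b.peptide_gene not in set(genes):
            raise ValueError(f"crosstalk peptide {b.peptide_gene!r} not in gene universe")
        if b.peptide_gene not in set(markers[b.source_cluster]):
            if b.peptide_gene in assigned:
                raise ValueError(
                    f"crosstalk peptide {b.peptide_gene!r} is already planted elsewhere; "
                    f"it must be (or become) a marker of {b.source_cluster!r}"
                )
            # the peptide must be a marker of its source cluster: plant it as one
            markers[b.source_cluster] = sorted(markers[b.source_cluster]
                                               + [b.peptide_gene])
            assigned.add(b.peptide_gene)
        missing = set(b.target_genes) - set(genes)
        if missing:
            raise ValueError(f"crosstalk targets absent from gene universe: {missing}")

    # -- baseline means
    lam = rngs["baseline"].lognormal(np.log(config.baseline_mean),
                                     config.baseline_sigma, config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    slope, mid = config.dropout_logit_slope, config.dropout_midpoint
    # DEGs sit on moderately expressed genes (baseline detection ~0.4-0.6)
    # so the planted truth is testable under the standard 30% prefilter
    deg_idx = degs["gene"].map(gene_pos).to_numpy()
    if len(deg_idx):
        target_fracs = rngs["baseline"].uniform(0.4, 0.6, len(deg_idx))
        lam[deg_idx] = [_solve_mean_for_fraction(f, config.dispersion, slope, mid)
                        for f in target_fracs]
    marker_in_mult = np.exp(config.marker_logfc)
    if config.marker_frac_in is not None:
        mu_out = _solve_mean_for_fraction(config.marker_frac_out or 0.1,
                                          config.dispersion, slope, mid)
        mu_in = _solve_mean_for_fraction(config.marker_frac_in,
                                         config.dispersion, slope, mid)
        for cl in labels:
            for g in markers[cl]:
                lam[gene_pos[g]] = mu_out

    # -- design: animals, cells, cluster assignment
    animals, animal_cond = [], {}
    for cond in config.conditions:
        for k in range(1, config.animals_per_condition + 1):
            a = f"{cond}{k}"
            animals.append(a)
            animal_cond[a] = cond
    n_cells = config.cells_per_animal * len(animals)
    cell_animal = np.repeat(animals, config.cells_per_animal)
    cell_cond = np.array([animal_cond[a] for a in cell_animal])
    cluster_idx = rngs["assign"].choice(config.n_clusters, size=n_cells,
                                        p=config.abundances())
    cell_cluster = np.array(labels, dtype=object)[cluster_idx]
    barcodes = pd.Index([f"{a}_{i:05d}" for i, a in enumerate(cell_animal)])

    # -- per-cell mean matrix
    mu = np.tile(lam[:, None], (1, n_cells))
    for ci, cl in enumerate(labels):
        in_cl = cluster_idx == ci
        if not in_cl.any():
            continue
        midx = np.array([gene_pos[g] for g in markers[cl]])
        if config.marker_frac_in is not None:
            mu[np.ix_(midx, in_cl)] = mu_in
        else:
            mu[np.ix_(midx, in_cl)] *= marker_in_mult
    is_tbi = cell_cond == config.conditions[1] if len(config.conditions) > 1 else \
        np.zeros(n_cells, dtype=bool)
    for _, row in degs.iterrows():
        gi = gene_pos[row["gene"]]
        in_scope = np.isin(cell_cluster, row["clusters"]) & is_tbi
        mu[gi, in_scope] *= np.exp(row["logfc"])

    animal_factor = {a: f for a, f in zip(
        animals, rngs["animal"].lognormal(0.0, config.animal_sigma, len(animals)))}
    mu *= np.array([animal_factor[a] for a in cell_animal])[None, :]

    tau = config.crosstalk_tau
    for b in config.crosstalk_blocks:
        z = {a: v for a, v in zip(animals, rngs["crosstalk"].normal(size=len(animals)))}
        w = rngs["crosstalk"].normal(size=(len(b.target_genes), len(animals)))
        z_cell = np.array([z[a] for a in cell_animal])
        src_cells = cell_cluster == b.source_cluster
        mu[gene_pos[b.peptide_gene], src_cells] *= np.exp(tau * z_cell[src_cells])
        tgt_cells = cell_cluster == b.target_cluster
        a_index = {a: i for i, a in enumerate(animals)}
        for tg_i, tg in enumerate(b.target_genes):
            latent = b.r * z_cell + np.sqrt(1.0 - b.r ** 2) * \
                w[tg_i, [a_index[a] for a in cell_animal]]
            mu[gene_pos[tg], tgt_cells] *= np.exp(tau * latent[tgt_cells])

    # -- counts: gamma-Poisson + logistic dropout
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        rates = rngs["counts"].gamma(shape, config.dispersion * mu)
        counts = rngs["counts"].poisson(rates)
    else:
        counts = rngs["counts"].poisson(mu)
    keep = rngs["dropout"].random(mu.shape) < _keep_prob(mu, slope, mid)
    counts = counts * keep

    m = CountMatrix(counts, genes, barcodes)
    meta = pd.DataFrame({"condition": cell_cond, "animal": cell_animal,
                         "cluster": cell_cluster}, index=barcodes)
    meta.index.name = "barcode"
    truth = GroundTruth(
        cell_clusters=pd.Series(cell_cluster, index=barcodes, name="cluster"),
        markers=markers, degs=degs, crosstalk=tuple(config.crosstalk_blocks),
    )
    truth.validate_against(m)
    return m, meta, truth


def generate_reference_sets(truth: GroundTruth, noise: float = 0.0,
                            seed: int = 0, universe=None) -> GeneSetCollection:
    """One reference marker set per cluster, optionally corrupted.

    With ``noise`` > 0, ``round(noise * set size)`` members of each set are
    replaced (seeded) by random genes that are markers of no cluster.
    """
    if not truth.markers:
        raise ValueError("empty ground truth")
    rng = np.random.default_rng(seed)
    all_markers = set().union(*truth.markers.values())
    if universe is None:
        universe = sorted(all_markers | set(truth.degs["gene"]))
    decoys = sorted(set(universe) - all_markers)
    sets, desc = {}, {}
    for cl, genes in sorted(truth.markers.items()):
        genes = list(genes)
        n_replace = int(round(noise * len(genes)))
        if n_replace:
            if n_replace > len(decoys):
                raise ValueError("not enough non-marker genes to corrupt the sets")
            drop = rng.choice(len(genes), size=n_replace, replace=False)
            keep = [g for i, g in enumerate(genes) if i not in set(drop.tolist())]
            noise_genes = rng.choice(decoys, size=n_replace, replace=False).tolist()
            genes = keep + noise_genes
        sets[f"ref_{cl}"] = genes
        desc[f"ref_{cl}"] = f"synthetic reference markers for {cl}"
    return GeneSetCollection(sets, desc, universe=set(universe))


def generate_spot_counts(n_cells: int, marker_low: float = 2.0,
                         marker_high: float = 30.0, high_weight: float = 0.5,
                         target_mean: float = 5.0, deg_effect: float = 0.0,
                         seed: int = 0, n_images: int = 8) -> pd.DataFrame:
    """Per-cell smFISH spot counts for a marker and a target gene.

    Marker counts come from a two-component Poisson mixture (low = off-type
    cells, high = the cell type of interest); ``deg_effect`` (ln units) shifts
    the target gene only in tbi cells of the high-marker component.
    """
    rng = np.random.default_rng(seed)
    cols = ["image_id", "group", "marker_count", "target_count"]
    if n_cells == 0:
        return pd.DataFrame(columns=cols)
    group = np.where(rng.random(n_cells) < 0.5, "sham", "tbi")
    high = rng.random(n_cells) < high_weight
    marker = rng.poisson(np.where(high, marker_high, marker_low))
    t_mean = target_mean * np.exp(np.where(high & (group == "tbi"), deg_effect, 0.0))
    target = rng.poisson(t_mean)
    return pd.DataFrame({
        "image_id": [f"img{(i % n_images):02d}" for i in range(n_cells)],
        "group": group, "marker_count": marker, "target_count": target,
    }, columns=cols)


def generate_animal_summaries(clusters, n_genes: int, n_animals: int,
                              blocks=(), base: float = 2.0,
                              noise_sd: float = 1.0, seed: int = 0) -> dict:
    """Animal-level genes x animals summary matrices with exact planted r.

    Every entry is ``base + noise_sd * N(0,1)`` i.i.d.; for each
    :class:`CrosstalkBlock`, the peptide row of the source cluster and the
    target rows of the target cluster share a latent animal factor so their
    population correlation is exactly ``block.r``.
    """
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"g{i:04d}" for i in range(n_genes)])
    animals = [f"a{i:02d}" for i in range(n_animals)]
    out = {cl: pd.DataFrame(base + noise_sd * rng.normal(size=(n_genes, n_animals)),
                            index=genes, columns=animals)
           for cl in clusters}
    latents = {}  # (source cluster, peptide) -> z, reused across blocks
    for b in blocks:
        if b.source_cluster not in out or b.target_cluster not in out:
            raise ValueError(f"block references unknown cluster: {b}")
        if b.peptide_gene not in genes or any(tg not in genes for tg in b.target_genes):
            raise ValueError(f"block names genes outside the universe: {b}")
        key = (b.source_cluster, b.peptide_gene)
        if key not in latents:
            latents[key] = rng.normal(size=n_animals)
        z = latents[key]
        out[b.source_cluster].loc[b.peptide_gene] = base + noise_sd * z
        for tg in b.target_genes:
            eps = rng.normal(size=n_animals)
            out[b.target_cluster].loc[tg] = base + noise_sd * (
                b.r * z + np.sqrt(1.0 - b.r ** 2) * eps)
    return out
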