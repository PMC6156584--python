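"""Digital gene expression (DGE) matrix I/O, cell quality filtering,
UMI normalization and per-animal summaries.

A DGE matrix is genes x cells of non-negative integer UMI counts, as produced
by droplet scRNA-seq pipelines. Two on-disk dialects are supported:

* ``mtx`` — a directory with ``matrix.mtx`` (MatrixMarket coordinate, 1-based),
  ``genes.tsv`` and ``barcodes.tsv``;
* ``dense_tsv`` — a single TSV with gene symbols in the first column and one
  column per cell barcode (the Drop-seq Tools ``DigitalExpression`` layout).

Cell quality control keeps cells with at least ``min_genes`` detected genes
and ``min_transcripts`` total UMIs (boundaries inclusive). Normalization is
counts-per-cell scaled to ``scale`` (default 10,000) and natural-log
transformed with pseudocount 1, so zeros stay zero.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

log = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "NormMatrix",
    "DGEFormatError",
    "EmptyResultError",
    "read_dge",
    "write_dge",
    "read_meta",
    "write_meta",
    "validate_meta",
    "filter_cells",
    "normalize",
    "summarize_by_animal",
    "pseudobulk",
]

META_COLUMNS = ("condition", "animal", "cluster")


class DGEFormatError(ValueError):
    """A DGE file violates the declared dialect."""


class EmptyResultError(ValueError):
    """An operation removed every cell (or was handed nothing)."""


def _unique_index(labels, what: str) -> pd.Index:
    idx = pd.Index(labels, dtype=object)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise DGEFormatError(f"duplicate {what} ids: {dups}")
    return idx


@dataclass
class CountMatrix:
    """Genes x cells UMI count matrix with symbol/barcode labels."""

    values: np.ndarray
    genes: pd.Index
    cells: pd.Index

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.genes = _unique_index(self.genes, "gene")
        self.cells = _unique_index(self.cells, "cell")
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise DGEFormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.values.size:
            bad = np.argwhere((self.values < 0) | (self.values != np.floor(self.values)))
            if len(bad):
                g, c = bad[0]
                raise DGEFormatError(
                    f"count for gene {self.genes[g]!r}, cell {self.cells[c]!r} is "
                    f"{self.values[g, c]!r}: counts must be non-negative integers"
                )
        self.values = self.values.astype(np.int64, copy=False)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.to_numpy(), df.index, df.columns)


@dataclass
class NormMatrix:
    """Genes x cells log-scale normalized expression; zeros are preserved."""

    values: np.ndarray
    genes: pd.Index
    cells: pd.Index
    provenance: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)


# ---------------------------------------------------------------------------
# readers / writers


def _read_dense_tsv(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.empty:
        raise DGEFormatError(f"{path}: no cell columns found (expected barcode header)")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        # locate the first non-numeric entry for the error message
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                i = int(np.argmax(coerced.isna().to_numpy()))
                raise DGEFormatError(
                    f"{path}: non-numeric entry {df.iat[i, j]!r} at gene "
                    f"{df.index[i]!r}, cell {col!r}"
                )
        raise DGEFormatError(f"{path}: non-numeric entries")
    try:
        return CountMatrix.from_frame(df)
    except DGEFormatError as exc:
        raise DGEFormatError(f"{path}: {exc}") from None


def _mtx_paths(path):
    return (
        os.path.join(path, "matrix.mtx"),
        os.path.join(path, "genes.tsv"),
        os.path.join(path, "barcodes.tsv"),
    )


def _read_mtx(path) -> CountMatrix:
    mtx, genes_f, cells_f = _mtx_paths(path)
    for f in (mtx, genes_f, cells_f):
        if not os.path.exists(f):
            raise DGEFormatError(f"missing {f}")
    mat = spio.mmread(mtx)
    genes = pd.read_csv(genes_f, sep="\t", header=None)[0]
    cells = pd.read_csv(cells_f, sep="\t", header=None)[0]
    dense = np.asarray(mat.todense()) if sparse.issparse(mat) else np.asarray(mat)
    try:
        return CountMatrix(dense, genes, cells)
    except DGEFormatError as exc:
        raise DGEFormatError(f"{mtx}: {exc}") from None


def read_dge(path, format: str = "auto") -> CountMatrix:
    """Read a DGE matrix in ``mtx`` or ``dense_tsv`` dialect."""
    if format == "auto":
        format = "mtx" if os.path.isdir(path) else "dense_tsv"
    if format == "mtx":
        return _read_mtx(path)
    if format == "dense_tsv":
        return _read_dense_tsv(path)
    raise ValueError(f"unknown DGE format {format!r}")


def write_dge(m: CountMatrix, path, format: str = "mtx") -> None:
    if format == "mtx":
        os.makedirs(path, exist_ok=True)
        mtx, genes_f, cells_f = _mtx_paths(path)
        spio.mmwrite(mtx, sparse.coo_matrix(m.values))
        pd.Series(m.genes).to_csv(genes_f, sep="\t", header=False, index=False)
        pd.Series(m.cells).to_csv(cells_f, sep="\t", header=False, index=False)
    elif format == "dense_tsv":
        df = m.to_frame()
        df.index.name = "GENE"
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown DGE format {format!r}")


def read_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    validate_meta(meta)
    return meta


def write_meta(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "barcode"
    out.to_csv(path, sep="\t")


def validate_meta(meta: pd.DataFrame, counts: CountMatrix | None = None,
                  conditions=None) -> None:
    """Check the per-cell metadata table (condition / animal / cluster)."""
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if meta.index.has_duplicates:
        raise ValueError("metadata has duplicate cell barcodes")
    if conditions is not None:
        bad = set(meta["condition"]) - set(conditions)
        if bad:
            raise ValueError(f"conditions {sorted(bad)} not in declared set {sorted(conditions)}")
    if counts is not None:
        missing_cells = counts.cells.difference(meta.index)
        if len(missing_cells):
            raise ValueError(
                f"{len(missing_cells)} cells in the matrix lack metadata rows "
                f"(e.g. {missing_cells[:3].tolist()})"
            )


# ---------------------------------------------------------------------------
# QC + normalization


def filter_cells(m: CountMatrix, min_genes: int = 500,
                 min_transcripts: int = 900) -> CountMatrix:
    """Keep cells with >= ``min_genes`` detected genes and >= ``min_transcripts``
    total UMIs (both inclusive)."""
    if m.n_cells == 0:
        raise EmptyResultError("filter_cells: matrix has no cells")
    genes_per_cell = (m.values > 0).sum(axis=0)
    umis_per_cell = m.values.sum(axis=0)
    keep = (genes_per_cell >= min_genes) & (umis_per_cell >= min_transcripts)
    n_removed = int((~keep).sum())
    log.info("filter_cells: removed %d / %d cells (min_genes=%d, min_transcripts=%d)",
             n_removed, m.n_cells, min_genes, min_transcripts)
    if not keep.any():
        raise EmptyResultError(
            f"filter_cells removed all {m.n_cells} cells at min_genes={min_genes}, "
            f"min_transcripts={min_transcripts}"
        )
    return CountMatrix(m.values[:, keep], m.genes, m.cells[keep])


def normalize(m: CountMatrix, scale: float = 10_000.0,
              pseudocount: float = 1.0) -> NormMatrix:
    """ln(pseudocount + count / cell_total * scale), per cell."""
    totals = m.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        raise ValueError(
            f"{len(zero)} cells have zero total UMIs (e.g. {m.cells[zero[:3]].tolist()}); "
            "run filter_cells first"
        )
    vals = np.log(pseudocount + m.values / totals * scale)
    if pseudocount == 1.0:
        vals[m.values == 0] = 0.0  # exact zero preservation
    return NormMatrix(vals, m.genes, m.cells,
                      provenance={"scale": scale, "log_base": "e",
                                  "pseudocount": pseudocount})


# ---------------------------------------------------------------------------
# summaries


def summarize_by_animal(n: NormMatrix, meta: pd.DataFrame,
                        cluster: str | None = None) -> pd.DataFrame:
    """Genes x animals matrix of mean normalized expression.

    With ``cluster`` given, only that cluster's cells contribute; animals with
    no cells in the cluster are absent from the output (and logged).
    """
    validate_meta(meta)
    meta = meta.loc[n.cells]
    if cluster is not None:
        known = set(meta["cluster"])
        if cluster not in known:
            raise ValueError(f"unknown cluster {cluster!r}; present: {sorted(known)}")
        mask = (meta["cluster"] == cluster).to_numpy()
    else:
        mask = np.ones(len(meta), dtype=bool)
    if not mask.any():
        raise EmptyResultError("no cells selected for summary")
    animals = meta["animal"].to_numpy()
    out = {}
    for animal in pd.unique(animals):
        sel = mask & (animals == animal)
        if not sel.any():
            log.info("summarize_by_animal: animal %s has no cells in cluster %s",
                     animal, cluster)
            continue
        out[animal] = n.values[:, sel].mean(axis=1)
    return pd.DataFrame(out, index=n.genes)


def pseudobulk(n: NormMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """In-silico bulk profile: per-animal mean over all cells, clusters pooled."""
    if len(meta) == 0:
        raise EmptyResultError("pseudobulk: empty metadata")
    return summarize_by_animal(n, meta, cluster=None)
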