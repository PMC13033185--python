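"""Count-matrix I/O and the standard scRNA-seq preprocessing recipe.

The pipeline consumes raw non-negative integer counts (cells × genes) and
produces the real-valued model input via: gene filtering (expressed in at
least ``min_cells`` cells), depth normalisation to a fixed scale followed by
log1p, and selection of the most highly variable genes by a mean-binned
normalised-dispersion statistic.
"""

from __future__ import annotations

import gzip
import json
import tarfile
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "load_counts",
    "filter_genes",
    "normalize_log",
    "select_hvg",
]

#: matrices denser than this are stored as ndarray, sparser as CSR
_SPARSE_DENSITY_CUTOFF = 0.5


def _maybe_sparse(values):
    """Store sparsely when density < 50% (scRNA-seq is typically >90% zero)."""
    if sp.issparse(values):
        dense_frac = values.nnz / max(1, values.shape[0] * values.shape[1])
        return values.tocsr() if dense_frac < _SPARSE_DENSITY_CUTOFF else np.asarray(values.todense())
    values = np.asarray(values)
    dense_frac = np.count_nonzero(values) / max(1, values.size)
    return sp.csr_matrix(values) if dense_frac < _SPARSE_DENSITY_CUTOFF else values


@dataclass
class CountMatrix:
    """Raw counts, cells × genes, with identifiers and optional labels."""

    values: object  # ndarray or csr_matrix, non-negative integers
    cell_ids: list[str]
    gene_ids: list[str]
    labels: Optional[list[str]] = None

    def __post_init__(self):
        self.values = _maybe_sparse(self.values)
        n, g = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} columns")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length does not match cell count")
        data = self.values.data if sp.issparse(self.values) else self.values
        if data.size and data.min() < 0:
            raise ValueError("count matrix contains negative entries")
        if data.size and np.any(data != np.round(data)):
            raise ValueError("count matrix contains non-integer entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        v = self.values
        return np.asarray(v.todense()) if sp.issparse(v) else np.asarray(v)


@dataclass
class ExpressionMatrix:
    """Normalised log-transformed expression restricted to selected genes."""

    values: np.ndarray  # cells × genes_selected, real
    size_factors: np.ndarray  # per cell, > 0
    hvg_index: np.ndarray  # indices into the gene list of the source counts
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.size_factors = np.asarray(self.size_factors, dtype=np.float64)
        self.hvg_index = np.asarray(self.hvg_index, dtype=np.int64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        if np.any(self.size_factors <= 0):
            raise ValueError("size factors must be positive")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def load_counts(path, format: str = None) -> CountMatrix:
    """Load a counts file into cells × genes orientation.

    Formats: ``mtx`` (MatrixMarket genes × cells, with ``barcodes.tsv`` and
    ``features.tsv``/``genes.tsv`` beside it — the 10x convention, transposed
    on read), ``csv`` (header row = gene ids, first column = cell ids) and
    ``dense`` (whitespace-separated numbers, ids autogenerated). When
    ``format`` is omitted it is inferred from the suffix.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"": "mtx", ".mtx": "mtx", ".csv": "csv", ".txt": "dense", ".tsv": "dense"}.get(
            suffix, "csv"
        )
    if format == "mtx":
        return _load_mtx(path)
    if format == "csv":
        return _load_csv(path)
    if format == "dense":
        return _load_dense(path)
    raise ValueError(f"unknown format {format!r}; expected mtx, csv or dense")


def _sidecar(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = directory / name
            if p.exists():
                return p
    raise FileNotFoundError(f"none of {stems} found beside matrix in {directory}")


def _read_tsv_column(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _load_mtx(path: Path) -> CountMatrix:
    if path.is_dir():
        matrix_path = _sidecar(path, ["matrix.mtx"])
        directory = path
    else:
        matrix_path = path
        directory = path.parent
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # noqa: BLE001 - report the parse failure location
        raise ValueError(f"malformed MatrixMarket file {matrix_path}: {exc}") from exc
    barcodes = _read_tsv_column(_sidecar(directory, ["barcodes.tsv", "cells.tsv"]))
    features = _read_tsv_column(_sidecar(directory, ["features.tsv", "genes.tsv"]))
    # MatrixMarket convention stores genes as rows; transpose to cells × genes
    mat = mat.T.tocsr()
    labels = None
    for cand in ("labels.csv", "labels.tsv"):
        p = directory / cand
        if p.exists():
            labels = _read_tsv_column(p) if cand.endswith("tsv") else [
                line.split(",")[0] for line in p.read_text().splitlines() if line.strip()
            ]
    return CountMatrix(values=mat, cell_ids=barcodes, gene_ids=features, labels=labels)


def _load_csv(path: Path) -> CountMatrix:
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    return CountMatrix(
        values=df.to_numpy(),
        cell_ids=[str(i) for i in df.index],
        gene_ids=[str(c) for c in df.columns],
    )


def _load_dense(path: Path) -> CountMatrix:
    try:
        arr = np.loadtxt(path, ndmin=2)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"malformed dense matrix {path}: {exc}") from exc
    n, g = arr.shape
    return CountMatrix(
        values=arr,
        cell_ids=[f"cell{i}" for i in range(n)],
        gene_ids=[f"gene{j}" for j in range(g)],
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def filter_genes(counts: CountMatrix, min_cells: int = 3) -> CountMatrix:
    """Keep genes with nonzero counts in at least ``min_cells`` cells."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    v = counts.values
    if sp.issparse(v):
        prevalence = np.asarray((v > 0).sum(axis=0)).ravel()
    else:
        prevalence = np.count_nonzero(v, axis=0)
    keep = prevalence >= min_cells
    if not keep.any():
        raise ValueError(
            f"no gene is expressed in >= {min_cells} cells; lower min_cells"
        )
    return CountMatrix(
        values=v[:, keep],
        cell_ids=counts.cell_ids,
        gene_ids=[g for g, k in zip(counts.gene_ids, keep) if k],
        labels=counts.labels,
    )


def normalize_log(counts: CountMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Depth-normalise each cell to ``scale`` total counts, then log1p."""
    dense = counts.dense().astype(np.float64)
    depth = dense.sum(axis=1)
    if np.any(depth <= 0):
        bad = [counts.cell_ids[i] for i in np.where(depth <= 0)[0]]
        raise ValueError(f"cells with zero total count: {bad}")
    size_factors = depth / scale
    values = np.log1p(dense / size_factors[:, None])
    return ExpressionMatrix(
        values=values,
        size_factors=size_factors,
        hvg_index=np.arange(dense.shape[1]),
        cell_ids=list(counts.cell_ids),
        gene_ids=list(counts.gene_ids),
    )


def select_hvg(expr: ExpressionMatrix, n_top: int = 2000, n_bins: int = 20) -> ExpressionMatrix:
    """Keep the ``n_top`` most variable genes.

    Variability is the normalised dispersion: dispersion = variance/mean on
    the log-expression values, z-scored within bins of genes of similar mean
    so that highly expressed genes do not dominate. Ties break by original
    gene order.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    X = expr.values
    n_genes = X.shape[1]
    if n_top >= n_genes:
        return expr
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    # bin genes by mean and z-score dispersion within each bin
    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, min(n_bins, n_genes))
    norm_disp = np.zeros(n_genes)
    for b in bins:
        d = dispersion[b]
        sd = d.std()
        norm_disp[b] = (d - d.mean()) / sd if sd > 0 else 0.0
    # stable sort on -score keeps the earlier gene on ties
    ranked = np.argsort(-norm_disp, kind="stable")
    keep = np.sort(ranked[:n_top])
    return ExpressionMatrix(
        values=X[:, keep],
        size_factors=expr.size_factors,
        hvg_index=expr.hvg_index[keep],
        cell_ids=list(expr.cell_ids),
        gene_ids=[expr.gene_ids[i] for i in keep] if expr.gene_ids else [],
    )


def preprocess(counts: CountMatrix, min_cells: int = 3, scale: float = 1e4,
               n_top: int = 2000) -> tuple[ExpressionMatrix, CountMatrix]:
    """Full recipe: filter → normalise/log → HVG.

    Returns the model input matrix and the raw counts restricted to the same
    filtered+selected genes (the reconstruction target of the ZINB decoder).
    """
    filtered = filter_genes(counts, min_cells=min_cells)
    expr = normalize_log(filtered, scale=scale)
    expr = select_hvg(expr, n_top=n_top)
    raw = CountMatrix(
        values=filtered.values[:, expr.hvg_index],
        cell_ids=filtered.cell_ids,
        gene_ids=[filtered.gene_ids[i] for i in expr.hvg_index],
        labels=filtered.labels,
    )
    return expr, raw


def save_processed(expr: ExpressionMatrix, raw: CountMatrix, path) -> None:
    """Write the processed matrix + metadata as a single .tar archive."""
    path = Path(path)
    buf_layout = {
        "expr.csv": pd.DataFrame(expr.values, index=expr.cell_ids, columns=expr.gene_ids),
        "raw.csv": pd.DataFrame(raw.dense(), index=raw.cell_ids, columns=raw.gene_ids),
    }
    meta = {
        "size_factors": expr.size_factors.tolist(),
        "hvg_index": expr.hvg_index.tolist(),
        "labels": raw.labels,
    }
    with tarfile.open(path, "w") as tar:
        for name, df in buf_layout.items():
            raw_bytes = df.to_csv().encode()
            info = tarfile.TarInfo(name)
            info.size = len(raw_bytes)
            tar.addfile(info, _io.BytesIO(raw_bytes))
        meta_bytes = json.dumps(meta).encode()
        info = tarfile.TarInfo("meta.json")
        info.size = len(meta_bytes)
        tar.addfile(info, _io.BytesIO(meta_bytes))


def load_processed(path) -> tuple[ExpressionMatrix, CountMatrix]:
    path = Path(path)
    with tarfile.open(path) as tar:
        expr_df = pd.read_csv(_io.BytesIO(tar.extractfile("expr.csv").read()), index_col=0)
        raw_df = pd.read_csv(_io.BytesIO(tar.extractfile("raw.csv").read()), index_col=0)
        meta = json.loads(tar.extractfile("meta.json").read())
    expr = ExpressionMatrix(
        values=expr_df.to_numpy(),
        size_factors=np.asarray(meta["size_factors"]),
        hvg_index=np.asarray(meta["hvg_index"]),
        cell_ids=[str(i) for i in expr_df.index],
        gene_ids=[str(c) for c in expr_df.columns],
    )
    raw = CountMatrix(
        values=raw_df.to_numpy(),
        cell_ids=[str(i) for i in raw_df.index],
        gene_ids=[str(c) for c in raw_df.columns],
        labels=meta["labels"],
    )
    return expr, raw
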