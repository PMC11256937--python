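"""Count-matrix I/O and the standard preprocessing recipe.

The recipe is: per-cell library-size normalization with a log1p transform,
variance-stabilizing selection of highly variable genes (HVGs), and per-gene
z-scoring of the HVG submatrix with an upper clip.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .errors import InputError, ValidationError

__all__ = [
    "CountMatrix",
    "ProcessedMatrix",
    "read_counts",
    "write_counts",
    "normalize_log",
    "select_hvgs",
    "scale_genes",
    "preprocess",
]


@dataclass
class CountMatrix:
    """Raw nonnegative-integer UMI counts, cells as rows.

    Attributes
    ----------
    counts
        ``(n_cells, n_genes)`` array or CSR matrix of nonnegative integers.
    cell_ids, gene_ids
        Unique identifiers for the row and column axes.
    """

    counts: np.ndarray | sp.spmatrix
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        n, g = self.counts.shape
        if n < 1 or g < 1:
            raise ValidationError(f"count matrix must be non-empty, got shape {(n, g)}")
        if len(self.cell_ids) != n:
            raise ValidationError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.gene_ids) != g:
            raise ValidationError(f"{len(self.gene_ids)} gene ids for {g} columns")
        if len(set(self.cell_ids)) != n:
            raise ValidationError("cell_ids are not unique")
        if len(set(self.gene_ids)) != g:
            raise ValidationError("gene_ids are not unique")
        _validate_integer_nonnegative(self.counts)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        """Counts as a dense float64 array (copies sparse input)."""
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=np.float64)
        return np.asarray(self.counts, dtype=np.float64)


@dataclass
class ProcessedMatrix:
    """Scaled expression restricted to selected HVG columns."""

    values: np.ndarray
    hvg_indices: np.ndarray
    per_gene_mean: np.ndarray = field(repr=False, default=None)
    per_gene_sd: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.hvg_indices = np.asarray(self.hvg_indices, dtype=np.int64)
        if len(np.unique(self.hvg_indices)) != self.hvg_indices.size:
            raise ValidationError("hvg_indices contain duplicates")
        if self.values.shape[1] != self.hvg_indices.size:
            raise ValidationError("values column count does not match hvg_indices")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_hvgs(self) -> int:
        return self.values.shape[1]


def _validate_integer_nonnegative(m: np.ndarray | sp.spmatrix) -> None:
    data = m.data if sp.issparse(m) else np.asarray(m)
    if data.size == 0:
        return
    if np.issubdtype(data.dtype, np.integer):
        bad = data < 0
    else:
        bad = (data < 0) | (data != np.floor(data)) | ~np.isfinite(data)
    if bad.any():
        if sp.issparse(m):
            coo = m.tocoo()
            mask = coo.data < 0 if np.issubdtype(coo.data.dtype, np.integer) else (
                (coo.data < 0) | (coo.data != np.floor(coo.data)) | ~np.isfinite(coo.data)
            )
            i = int(np.argmax(mask))
            raise ValidationError(
                f"non-integer or negative count {coo.data[i]!r} at "
                f"(cell {coo.row[i]}, gene {coo.col[i]})"
            )
        idx = np.argwhere(bad)
        r, c = idx[0]
        raise ValidationError(
            f"non-integer or negative count {np.asarray(m)[r, c]!r} at (cell {r}, gene {c})"
        )


def _find_sidecar(directory: str, stems: tuple[str, ...]) -> str:
    for stem in stems:
        for ext in (".tsv", ".txt", ".csv", ""):
            cand = os.path.join(directory, stem + ext)
            if os.path.isfile(cand):
                return cand
    raise InputError(f"no sidecar file matching {stems} in {directory}")


def read_counts(
    path: str,
    format: str | None = None,
    cells_as_rows: bool | None = None,
) -> CountMatrix:
    """Read a count matrix from MTX (with barcode/feature sidecars), CSV/TSV or HDF5.

    Parameters
    ----------
    path
        File to read. For ``mtx``, sidecar ``barcodes.tsv`` and
        ``features.tsv``/``genes.tsv`` files must live in the same directory.
    format
        One of ``{"mtx", "csv", "h5"}``; inferred from the extension when omitted.
    cells_as_rows
        Orientation of the stored matrix. Defaults: ``False`` for MTX (the
        common genes-by-cells convention), ``True`` for CSV and HDF5. The
        returned matrix always has cells as rows.
    """
    if not os.path.isfile(path):
        raise InputError(f"no such file: {path}")
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = {"mtx": "mtx", "csv": "csv", "tsv": "csv", "txt": "csv",
                  "h5": "h5", "hdf5": "h5", "h5ad": "h5"}.get(ext)
        if format is None:
            raise InputError(f"cannot infer format from extension of {path}")
    if format not in ("mtx", "csv", "h5"):
        raise InputError(f"unknown format {format!r}; expected mtx, csv or h5")

    if format == "mtx":
        if cells_as_rows is None:
            cells_as_rows = False
        mat = mmread(path)
        mat = sp.csr_matrix(mat)
        directory = os.path.dirname(os.path.abspath(path))
        barcodes_path = _find_sidecar(directory, ("barcodes",))
        features_path = _find_sidecar(directory, ("features", "genes"))
        barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
        features = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str).tolist()
        if not cells_as_rows:
            mat = sp.csr_matrix(mat.T)
        _validate_integer_nonnegative(mat)
        mat = mat.astype(np.int64)
        return CountMatrix(mat, cell_ids=barcodes, gene_ids=features)

    if format == "csv":
        if cells_as_rows is None:
            cells_as_rows = True
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy()
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
        if not cells_as_rows:
            values = values.T
            row_ids, col_ids = col_ids, row_ids
        _validate_integer_nonnegative(values)
        return CountMatrix(values.astype(np.int64), cell_ids=row_ids, gene_ids=col_ids)

    # h5: datasets /X (dense) or /X_data,/X_indices,/X_indptr (CSR), /obs_names, /var_names
    import h5py

    if cells_as_rows is None:
        cells_as_rows = True
    with h5py.File(path, "r") as f:
        obs = [b.decode() if isinstance(b, bytes) else str(b) for b in f["obs_names"][...]]
        var = [b.decode() if isinstance(b, bytes) else str(b) for b in f["var_names"][...]]
        if "X" in f:
            values: np.ndarray | sp.spmatrix = np.asarray(f["X"][...])
        else:
            shape = tuple(f.attrs["shape"]) if "shape" in f.attrs else (len(obs), len(var))
            values = sp.csr_matrix(
                (f["X_data"][...], f["X_indices"][...], f["X_indptr"][...]), shape=shape
            )
    if not cells_as_rows:
        values = values.T
        obs, var = var, obs
    _validate_integer_nonnegative(values)
    if sp.issparse(values):
        values = sp.csr_matrix(values).astype(np.int64)
    else:
        values = values.astype(np.int64)
    return CountMatrix(values, cell_ids=obs, gene_ids=var)


def write_counts(cm: CountMatrix, path: str, format: str = "mtx",
                 cells_as_rows: bool | None = None) -> None:
    """Write a CountMatrix in any of the three supported formats."""
    if format == "mtx":
        if cells_as_rows is None:
            cells_as_rows = False
        mat = sp.coo_matrix(cm.counts if cells_as_rows else cm.counts.T)
        mmwrite(path, mat, field="integer")
        directory = os.path.dirname(os.path.abspath(path))
        pd.Series(cm.cell_ids).to_csv(os.path.join(directory, "barcodes.tsv"),
                                      sep="\t", index=False, header=False)
        pd.Series(cm.gene_ids).to_csv(os.path.join(directory, "features.tsv"),
                                      sep="\t", index=False, header=False)
    elif format == "csv":
        df = pd.DataFrame(cm.dense().astype(np.int64), index=cm.cell_ids, columns=cm.gene_ids)
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        df.to_csv(path, sep=sep)
    elif format == "h5":
        import h5py

        with h5py.File(path, "w") as f:
            if sp.issparse(cm.counts):
                csr = sp.csr_matrix(cm.counts)
                f.create_dataset("X_data", data=csr.data)
                f.create_dataset("X_indices", data=csr.indices)
                f.create_dataset("X_indptr", data=csr.indptr)
                f.attrs["shape"] = csr.shape
            else:
                f.create_dataset("X", data=np.asarray(cm.counts, dtype=np.int64))
            f.create_dataset("obs_names", data=np.array(cm.cell_ids, dtype="S"))
            f.create_dataset("var_names", data=np.array(cm.gene_ids, dtype="S"))
    else:
        raise InputError(f"unknown format {format!r}")


def normalize_log(counts: CountMatrix, scale_factor: float = 1e4) -> np.ndarray:
    """Library-size normalize each cell to ``scale_factor`` and apply log1p.

    Entry ``(n, g)`` becomes ``ln(1 + count / cellsum_n * scale_factor)``.
    Cells with zero total count map to all-zero rows (with a warning).
    """
    if scale_factor <= 0:
        raise ValidationError(f"scale_factor must be positive, got {scale_factor}")
    x = counts.dense()
    cellsum = x.sum(axis=1)
    zero = cellsum == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cell(s) have zero total count; "
                      "their normalized rows are all zero")
    safe = np.where(zero, 1.0, cellsum)
    return np.log1p(x / safe[:, None] * scale_factor)


def select_hvgs(counts: CountMatrix, n_hvg: int = 4000, span: float = 0.3) -> np.ndarray:
    """Rank genes by variance-stabilized standardized variance; return top indices.

    A lowess fit of log10(variance) on log10(mean) over genes with positive
    variance predicts each gene's expected sd; raw counts are standardized by
    it, clipped at sqrt(N), and genes are ranked by the variance of the
    clipped values. Returns ``min(n_hvg, G)`` unique indices, best first.
    """
    if n_hvg < 1:
        raise ValidationError(f"n_hvg must be >= 1, got {n_hvg}")
    x = counts.dense()
    n = x.shape[0]
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    if not (var > 0).any():
        raise ValidationError("all genes have zero variance; no variable genes")

    positive = (mean > 0) & (var > 0)
    score = np.zeros(x.shape[1])
    if positive.sum() >= 2:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        lx = np.log10(mean[positive])
        ly = np.log10(var[positive])
        fitted = lowess(ly, lx, frac=span, return_sorted=False)
        expected_sd = np.sqrt(10.0 ** fitted)
        clip = np.sqrt(n)
        sub = x[:, positive]
        standardized = (sub - mean[positive]) / expected_sd
        np.clip(standardized, None, clip, out=standardized)
        score[positive] = standardized.var(axis=0, ddof=1)
    else:
        score[positive] = var[positive]

    k = min(n_hvg, x.shape[1])
    order = np.argsort(-score, kind="stable")
    return order[:k].astype(np.int64)


def scale_genes(normalized: np.ndarray, hvg_indices: np.ndarray,
                clip_max: float = 10.0) -> ProcessedMatrix:
    """Per-gene z-score of the HVG submatrix, upper-clipped at ``clip_max``.

    Uses the sample sd (``ddof=1``). Constant genes become zero columns.
    """
    hvg_indices = np.asarray(hvg_indices, dtype=np.int64)
    g = normalized.shape[1]
    if hvg_indices.size and (hvg_indices.min() < 0 or hvg_indices.max() >= g):
        raise ValidationError("hvg_indices out of range")
    sub = normalized[:, hvg_indices]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1) if sub.shape[0] > 1 else np.zeros(sub.shape[1])
    constant = sd == 0
    safe_sd = np.where(constant, 1.0, sd)
    scaled = (sub - mean) / safe_sd
    scaled[:, constant] = 0.0
    np.clip(scaled, None, clip_max, out=scaled)
    return ProcessedMatrix(values=scaled, hvg_indices=hvg_indices,
                           per_gene_mean=mean, per_gene_sd=sd)


def preprocess(counts: CountMatrix, n_hvg: int = 4000, scale_factor: float = 1e4,
               clip_max: float = 10.0) -> tuple[ProcessedMatrix, np.ndarray]:
    """Full recipe: normalize + log, select HVGs, scale.

    Returns the ProcessedMatrix (encoder input) and the raw counts restricted
    to the same HVG columns (the Poisson reconstruction target).
    """
    normalized = normalize_log(counts, scale_factor=scale_factor)
    hvg = select_hvgs(counts, n_hvg=n_hvg)
    processed = scale_genes(normalized, hvg, clip_max=clip_max)
    raw_hvg = counts.dense()[:, hvg]
    return processed, raw_hvg
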