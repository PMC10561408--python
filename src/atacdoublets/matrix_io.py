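"""Reading, writing and preprocessing of scCAS count matrices.

Single-cell chromatin accessibility data arrive as a sparse droplet-by-peak
count matrix, conventionally shipped as a Matrix Market (.mtx) triplet file
with companion barcode and peak TSVs (10x-style directory).  This module
loads that format (tolerating either on-disk orientation), applies the
standard preprocessing — removal of peaks open in fewer than a given
fraction of droplets, TF-IDF normalization — and provides the binarized
view needed for Jaccard-distance embeddings.

The TF-IDF transform used throughout is

    X'_{i,j} = X_{i,j} / sum_p X_{i,p} * log((1 + P) / sum_n X_{n,j})

i.e. term frequency within a droplet times the log inverse "document"
frequency of the peak, with P the number of peaks.  Zero entries stay zero,
so the sparsity pattern is preserved.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "MatrixFormatError",
    "read_counts",
    "read_dense_tsv",
    "write_counts",
    "filter_peaks",
    "filter_droplets",
    "tfidf",
    "binarize",
]


class MatrixFormatError(ValueError):
    """Raised when an on-disk matrix does not match its companion files."""


@dataclass
class CountMatrix:
    """Sparse non-negative droplet-by-peak count matrix.

    Rows are droplets (barcodes), columns are peaks.  Internal indices are
    0-based regardless of the 1-based Matrix Market convention on disk.
    """

    values: sp.csr_matrix
    barcodes: np.ndarray
    peaks: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.peaks = np.asarray(self.peaks, dtype=object)
        n, p = self.values.shape
        if len(self.barcodes) != n:
            raise MatrixFormatError(
                f"matrix has {n} rows but {len(self.barcodes)} barcodes"
            )
        if len(self.peaks) != p:
            raise MatrixFormatError(
                f"matrix has {p} columns but {len(self.peaks)} peak ids"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("count matrix contains negative entries")
        if len(set(self.barcodes)) != n:
            raise ValueError("droplet barcodes are not unique")

    @property
    def n_droplets(self) -> int:
        return self.values.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.values.shape[1]

    def subset_droplets(self, idx: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.values[idx], self.barcodes[idx], self.peaks)


@dataclass
class NormalizedMatrix:
    """TF-IDF-normalized matrix; same shape and identifiers as its source."""

    values: sp.csr_matrix
    barcodes: np.ndarray
    peaks: np.ndarray

    @property
    def n_droplets(self) -> int:
        return self.values.shape[0]


def _read_ids(path: str) -> np.ndarray:
    """First whitespace-free column of a TSV, one identifier per line."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].to_numpy(dtype=object)


def read_counts(matrix_path: str, barcodes_path: str, peaks_path: str) -> CountMatrix:
    """Load an MTX triplet file with its barcode and peak companions.

    On-disk orientation is auto-detected: if the matrix is peaks-by-droplets
    it is transposed so that rows are droplets.  Entries must be
    non-negative integers.
    """
    mat = mmread(matrix_path)
    barcodes = _read_ids(barcodes_path)
    peaks = _read_ids(peaks_path)
    nb, npk = len(barcodes), len(peaks)
    if mat.shape == (nb, npk):
        pass
    elif mat.shape == (npk, nb):
        mat = mat.T
    else:
        raise MatrixFormatError(
            f"matrix shape {mat.shape} matches neither {nb} barcodes x "
            f"{npk} peaks nor its transpose"
        )
    mat = sp.csr_matrix(mat)
    if mat.nnz:
        if mat.data.min() < 0:
            raise ValueError("count matrix contains negative entries")
        if not np.allclose(mat.data, np.round(mat.data)):
            raise ValueError("count matrix contains non-integer entries")
    mat = mat.astype(np.int64)
    return CountMatrix(mat, barcodes, peaks)


def read_dense_tsv(path: str) -> CountMatrix:
    """Read a small dense TSV matrix (header = peak ids, first column = barcodes)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = sp.csr_matrix(df.to_numpy(dtype=np.int64))
    return CountMatrix(values, df.index.to_numpy(dtype=object),
                       df.columns.to_numpy(dtype=object))


def write_counts(cm: CountMatrix, out_dir: str) -> None:
    """Write matrix.mtx + barcodes.tsv + peaks.tsv into ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    mmwrite(os.path.join(out_dir, "matrix.mtx"), cm.values.tocoo(), field="integer")
    for name, ids in (("barcodes.tsv", cm.barcodes), ("peaks.tsv", cm.peaks)):
        with open(os.path.join(out_dir, name), "w") as fh:
            fh.write("\n".join(map(str, ids)) + "\n")


def filter_peaks(cm: CountMatrix, min_frac: float = 0.01) -> CountMatrix:
    """Keep peaks open (count > 0) in at least ``min_frac`` of droplets.

    The default 1% cut is the conventional noise filter for droplet
    scATAC-seq count matrices.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    n = cm.n_droplets
    open_per_peak = (cm.values > 0).sum(axis=0).A1
    keep = open_per_peak >= min_frac * n
    if not keep.any():
        raise ValueError(
            "peak filter removed every peak; lower min_frac "
            f"(currently {min_frac})"
        )
    return CountMatrix(cm.values[:, keep].tocsr(), cm.barcodes, cm.peaks[keep])


def filter_droplets(cm: CountMatrix, min_counts: int = 1,
                    min_peaks: int = 0) -> CountMatrix:
    """Drop droplets below a total-count / open-peak floor.

    By default only all-zero droplets are removed, the minimum QC required
    for TF-IDF (positive row sums).
    """
    totals = cm.values.sum(axis=1).A1
    n_open = (cm.values > 0).sum(axis=1).A1
    keep = (totals >= min_counts) & (n_open >= min_peaks)
    if not keep.any():
        raise ValueError("droplet QC removed every droplet")
    return cm.subset_droplets(np.flatnonzero(keep))


def tfidf(cm: CountMatrix) -> NormalizedMatrix:
    """TF-IDF normalization of the count matrix (natural log).

    Requires every row and column sum to be positive; run
    :func:`filter_peaks` and :func:`filter_droplets` first.
    """
    X = cm.values.astype(np.float64)
    row_sums = X.sum(axis=1).A1
    col_sums = X.sum(axis=0).A1
    if (row_sums == 0).any():
        bad = int(np.flatnonzero(row_sums == 0)[0])
        raise ValueError(f"droplet {bad} has zero total count; apply droplet QC")
    if (col_sums == 0).any():
        bad = int(np.flatnonzero(col_sums == 0)[0])
        raise ValueError(f"peak {bad} has zero total count; apply peak filter")
    P = cm.n_peaks
    idf = np.log((1.0 + P) / col_sums)
    out = sp.diags(1.0 / row_sums) @ X
    out = (out @ sp.diags(idf)).tocsr()
    return NormalizedMatrix(out, cm.barcodes, cm.peaks)


def binarize(cm: CountMatrix) -> CountMatrix:
    """Replace every positive count with 1 (accessibility indicator)."""
    out = cm.values.copy()
    out.data = np.ones_like(out.data)
    return CountMatrix(out, cm.barcodes, cm.peaks)
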