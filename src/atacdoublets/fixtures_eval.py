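"""Synthetic scCAS benchmark generation and doublet-detection metrics.

The generator emulates the regimes of droplet scATAC-seq count matrices:
a handful of cell types with imbalanced proportions, each owning a block of
preferentially accessible peaks; near-binary counts; per-droplet sparsity
around 0.98.  Counts for a droplet of type t are independent
Poisson(depth * w_t[j]) draws, where the weight vector w_t mixes a uniform
distribution over the type's peak block (weight ``specificity``) with a
uniform background over all peaks — equivalent to a multinomial over w_t
with a Poisson-distributed total depth, which gives the closed-form
per-peak openness probability 1 - exp(-depth * w) used in the tests.

Ground-truth heterotypic doublets are planted by drawing two distinct cell
types with probability proportional to their proportions (mirroring how
real doublets form more often between abundant types), summing one random
singlet profile of each (read mixing), and optionally thinning the doublet's
counts binomially: a down-sampling rate r means each read is REMOVED with
probability r, i.e. doublets keep a fraction (1 - r) of their reads.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import average_precision_score, roc_auc_score

from .matrix_io import CountMatrix, write_counts

__all__ = [
    "SyntheticDataset",
    "MetricsReport",
    "generate_singlets",
    "plant_doublets",
    "standard_fixture",
    "evaluate",
    "write_dataset",
    "read_truth",
]


@dataclass
class SyntheticDataset:
    """A seeded synthetic count matrix with ground-truth doublet labels."""

    counts: CountMatrix
    cell_type: np.ndarray
    is_doublet: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_droplets(self) -> int:
        return self.counts.n_droplets


@dataclass
class MetricsReport:
    """Detection metrics: ranking (AUROC/AUPRC) plus calls at a calling rate."""

    auroc: float
    auprc: float
    precision: float
    recall: float
    f1: float
    calling_rate: float
    n_called: int


def _allocate(n: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n cells across type proportions."""
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def generate_singlets(n_singlets: int, n_types: int, proportions,
                      n_peaks: int, mean_depth: float,
                      specificity: float, seed: int) -> SyntheticDataset:
    """Generate a singlet-only synthetic dataset.

    Each cell type owns a contiguous block of ``n_peaks // n_types`` peaks;
    a droplet of that type spreads ``specificity`` of its read mass
    uniformly over the block and the rest uniformly over all peaks.
    """
    proportions = np.asarray(proportions, dtype=float)
    if len(proportions) != n_types:
        raise ValueError("need one proportion per cell type")
    if not math.isclose(proportions.sum(), 1.0, abs_tol=1e-8):
        raise ValueError("proportions must sum to 1")
    if not 0 <= specificity <= 1:
        raise ValueError("specificity must be in [0, 1]")
    if n_peaks < n_types:
        raise ValueError("need at least one peak per cell type")
    rng = np.random.default_rng(seed)
    block = n_peaks // n_types
    type_counts = _allocate(n_singlets, proportions)
    rows, labels = [], []
    for t in range(n_types):
        w = np.full(n_peaks, (1.0 - specificity) / n_peaks)
        w[t * block:(t + 1) * block] += specificity / block
        lam = mean_depth * w
        nt = type_counts[t]
        chunk = max(1, int(2e7) // n_peaks)
        for start in range(0, nt, chunk):
            m = min(chunk, nt - start)
            rows.append(sp.csr_matrix(rng.poisson(lam, size=(m, n_peaks))))
        labels.extend([f"type{t}"] * nt)
    counts = sp.vstack(rows).tocsr().astype(np.int64)
    barcodes = np.array([f"cell_{i:05d}" for i in range(n_singlets)], dtype=object)
    peaks = np.array([f"peak_{j:06d}" for j in range(n_peaks)], dtype=object)
    params = {"n_singlets": n_singlets, "n_types": n_types,
              "proportions": proportions.tolist(), "n_peaks": n_peaks,
              "mean_depth": mean_depth, "specificity": specificity,
              "seed": seed}
    return SyntheticDataset(CountMatrix(counts, barcodes, peaks),
                            np.array(labels, dtype=object),
                            np.zeros(n_singlets, dtype=bool), params)


def expected_sparsity(n_types: int, proportions, n_peaks: int,
                      mean_depth: float, specificity: float) -> float:
    """Analytic expected fraction of zero entries of the singlet matrix."""
    proportions = np.asarray(proportions, dtype=float)
    block = n_peaks // n_types
    total = 0.0
    for t in range(n_types):
        w = np.full(n_peaks, (1.0 - specificity) / n_peaks)
        w[t * block:(t + 1) * block] += specificity / block
        total += proportions[t] * np.exp(-mean_depth * w).sum()
    return total / n_peaks


def plant_doublets(ds: SyntheticDataset, doublet_rate: float,
                   weighted: bool = True, downsample_rate: float = 0.0,
                   seed: int = 0) -> SyntheticDataset:
    """Append floor(doublet_rate * n_singlets) heterotypic doublets.

    Parent cell types are drawn sequentially without replacement with
    probability proportional to the realized type proportions (or uniformly
    over distinct type pairs when ``weighted=False``); one singlet of each
    type is chosen uniformly and their count profiles summed.
    ``downsample_rate`` r in [0, 1) removes each doublet read independently
    with probability r (binomial thinning), emulating doublets whose read
    enrichment over singlets is weaker.  Singlet rows are left untouched.
    """
    if ds.is_doublet.any():
        raise ValueError("dataset already contains doublets")
    if not 0 < doublet_rate < 1:
        raise ValueError("doublet_rate must be in (0, 1)")
    if not 0 <= downsample_rate < 1:
        raise ValueError("downsample_rate must be in [0, 1)")
    types, type_counts = np.unique(ds.cell_type, return_counts=True)
    if len(types) < 2:
        raise ValueError("need at least two cell types to form heterotypic doublets")
    rng = np.random.default_rng(seed)
    n_singlets = ds.n_droplets
    n_doub = math.floor(doublet_rate * n_singlets)
    members = {t: np.flatnonzero(ds.cell_type == t) for t in types}
    w = type_counts / type_counts.sum()
    profiles, pair_labels = [], []
    for _ in range(n_doub):
        if weighted:
            a = rng.choice(len(types), p=w)
            w2 = w.copy()
            w2[a] = 0.0
            b = rng.choice(len(types), p=w2 / w2.sum())
        else:
            a, b = rng.choice(len(types), size=2, replace=False)
        pa = rng.choice(members[types[a]])
        pb = rng.choice(members[types[b]])
        prof = (ds.counts.values[pa] + ds.counts.values[pb]).tocsr()
        if downsample_rate > 0:
            prof.data = rng.binomial(prof.data, 1.0 - downsample_rate)
            prof.eliminate_zeros()
        profiles.append(prof)
        pair_labels.append(f"{types[a]}+{types[b]}")
    counts = sp.vstack([ds.counts.values] + profiles).tocsr()
    barcodes = np.concatenate([
        ds.counts.barcodes,
        np.array([f"doublet_{i:05d}" for i in range(n_doub)], dtype=object)])
    params = dict(ds.params, doublet_rate=doublet_rate, weighted=weighted,
                  downsample_rate=downsample_rate, doublet_seed=seed)
    return SyntheticDataset(
        CountMatrix(counts, barcodes, ds.counts.peaks),
        np.concatenate([ds.cell_type, np.array(pair_labels, dtype=object)]),
        np.concatenate([ds.is_doublet, np.ones(n_doub, dtype=bool)]),
        params)


def standard_fixture(seed: int = 7, downsample_rate: float = 0.0,
                     n_singlets: int = 2000, n_peaks: int = 50_000,
                     doublet_rate: float = 0.2) -> SyntheticDataset:
    """The package's standard planted benchmark.

    Five cell types with proportions (0.35, 0.25, 0.2, 0.12, 0.08), 2,000
    singlets over 50,000 peaks at mean depth 1,000 and specificity 0.8
    (realized sparsity ~0.98), plus 20% proportion-weighted heterotypic
    doublets.  When ``n_peaks`` is reduced for a scaled-down run the mean
    depth shrinks proportionally (depth = 0.02 * n_peaks), preserving the
    per-peak Poisson rates and hence the sparsity regime.
    """
    ds = generate_singlets(
        n_singlets=n_singlets, n_types=5,
        proportions=(0.35, 0.25, 0.2, 0.12, 0.08),
        n_peaks=n_peaks, mean_depth=0.02 * n_peaks, specificity=0.8, seed=seed)
    return plant_doublets(ds, doublet_rate=doublet_rate, weighted=True,
                          downsample_rate=downsample_rate, seed=seed + 1)


def evaluate(scores: np.ndarray, truth: np.ndarray,
             calling_rate: float) -> MetricsReport:
    """AUROC, AUPRC and the calling-rate confusion metrics.

    AUROC is the rank statistic with ties averaged; AUPRC the step-wise
    precision-recall integral.  Precision/recall/F1 come from flagging the
    top floor(calling_rate * N) droplets by score (ties at the cutoff
    broken by droplet index).
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth, dtype=bool)
    if len(scores) != len(truth):
        raise ValueError("scores and truth must be aligned")
    if truth.all() or not truth.any():
        raise ValueError("truth labels are degenerate (single class)")
    if not 0 < calling_rate < 1:
        raise ValueError("calling_rate must be in (0, 1)")
    auroc = float(roc_auc_score(truth, scores))
    auprc = float(average_precision_score(truth, scores))
    n_call = math.floor(calling_rate * len(scores))
    order = np.argsort(-scores, kind="stable")
    called = np.zeros(len(scores), dtype=bool)
    called[order[:n_call]] = True
    tp = int((called & truth).sum())
    precision = tp / n_call if n_call else 0.0
    recall = tp / int(truth.sum())
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return MetricsReport(auroc, auprc, precision, recall, f1,
                         calling_rate, n_call)


def write_dataset(ds: SyntheticDataset, out_dir: str) -> None:
    """Write matrix.mtx, barcodes.tsv, peaks.tsv, truth.tsv and params.json."""
    write_counts(ds.counts, out_dir)
    pd.DataFrame({"barcode": ds.counts.barcodes,
                  "cell_type": ds.cell_type,
                  "is_doublet": ds.is_doublet.astype(int)}
                 ).to_csv(os.path.join(out_dir, "truth.tsv"),
                          sep="\t", index=False)
    with open(os.path.join(out_dir, "params.json"), "w") as fh:
        json.dump(ds.params, fh, indent=2)


def read_truth(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_doublet"] = df["is_doublet"].astype(bool)
    return df
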