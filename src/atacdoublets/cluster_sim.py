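"""Density clustering of active droplets and simulation of artificial doublets.

The detector's training signal comes from artificial doublets simulated each
iteration from the droplets not yet flagged.  To enrich for *heterotypic*
doublets — the detectable, harmful kind — active droplets are first
clustered (PCA -> UMAP -> DBSCAN) and most artificial doublets are formed by
drawing two distinct clusters with probability proportional to cluster size
and merging one random member of each.  The remainder are classical random
pairs.  Per iteration the simulated count is floor(0.3 * n_active), of which
70% are cluster-weighted heterotypic and 30% random pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import DBSCAN

from .knn_graph import NOISE, Embedding, pca_umap
from .matrix_io import CountMatrix, NormalizedMatrix

__all__ = [
    "ClusterLabels",
    "SimulatedDoublets",
    "SingleClusterError",
    "embed_for_clustering",
    "dbscan_cluster",
    "default_min_samples",
    "sample_cluster_pair",
    "simulate_doublets",
]

HET_FRACTION = 0.7     # share of simulated doublets that are cluster-weighted
SIM_FRACTION = 0.3     # simulated doublets per active droplet


class SingleClusterError(ValueError):
    """Fewer than two clusters: heterotypic pairing is undefined."""


@dataclass
class ClusterLabels:
    """DBSCAN labels per active droplet; noise carries the sentinel -1."""

    labels: np.ndarray
    sizes: dict[int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        ids, counts = np.unique(self.labels[self.labels != NOISE],
                                return_counts=True)
        self.sizes = dict(zip(ids.tolist(), counts.tolist()))
        if not self.sizes:
            raise ValueError("clustering produced no non-noise cluster")

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


@dataclass
class SimulatedDoublets:
    """Artificial doublet profiles with their parent indices and mode."""

    profiles: sp.csr_matrix
    parents: np.ndarray          # (n_sim, 2) indices into the active matrix
    mode: np.ndarray             # "heterotypic" | "random" per row

    @property
    def n_sim(self) -> int:
        return self.profiles.shape[0]


def embed_for_clustering(Xn: NormalizedMatrix, n_pcs: int = 30,
                         seed: int = 0) -> Embedding:
    """2-D embedding (SVD then UMAP) of the normalized active droplets."""
    return Embedding(pca_umap(Xn.values, n_pcs, seed, n_dims=2), "pca")


def default_min_samples(n_active: int) -> int:
    """DBSCAN min_samples: 0.5% of the input droplets, floored at 5."""
    return max(5, int(np.floor(0.005 * n_active)))


def dbscan_cluster(emb: Embedding | np.ndarray, eps: float = 0.1,
                   min_samples: int | None = None) -> ClusterLabels:
    """DBSCAN on the 2-D embedding (eps 0.1, adaptive min_samples).

    If every point is labeled noise, falls back to a single cluster holding
    all points (with a warning) so the pipeline can proceed in random mode.
    """
    coords = emb.coords if isinstance(emb, Embedding) else np.asarray(emb, float)
    n = coords.shape[0]
    if min_samples is None:
        min_samples = default_min_samples(n)
    if n < min_samples:
        raise ValueError(f"need at least min_samples={min_samples} points")
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(coords)
    if (labels == NOISE).all():
        warnings.warn("DBSCAN labeled every droplet noise; "
                      "falling back to a single cluster")
        labels = np.zeros(n, dtype=int)
    return ClusterLabels(labels)


def sample_cluster_pair(labels: ClusterLabels,
                        rng: np.random.Generator) -> tuple[int, int]:
    """Draw two distinct clusters, each with probability ~ its size.

    Sequential draw without replacement of cluster ids.  Raises
    :class:`SingleClusterError` with fewer than two clusters, signalling
    the random-mode fallback to the caller.
    """
    if labels.n_clusters < 2:
        raise SingleClusterError("cluster-weighted pairing needs >= 2 clusters")
    ids = np.fromiter(labels.sizes.keys(), dtype=int)
    w = np.fromiter(labels.sizes.values(), dtype=float)
    first = rng.choice(ids, p=w / w.sum())
    rest = ids != first
    ids2, w2 = ids[rest], w[rest]
    second = rng.choice(ids2, p=w2 / w2.sum())
    return int(first), int(second)


def _combine(a: sp.spmatrix, b: sp.spmatrix, how: str) -> sp.spmatrix:
    if how == "sum":
        return a + b
    if how == "max":
        return a.maximum(b)
    raise ValueError(f"unknown combine rule {how!r}")


def simulate_doublets(X: CountMatrix, labels: ClusterLabels,
                      rng: np.random.Generator,
                      combine: str = "sum") -> SimulatedDoublets:
    """Simulate floor(0.3 * n_active) artificial doublets from active droplets.

    round(0.7 * n_sim) are heterotypic — parents drawn from two
    size-weighted distinct clusters — and the rest are random pairs of
    distinct active droplets.  Each profile is the element-wise combination
    (default: sum, i.e. read mixing) of its parents' count vectors.  With a
    single cluster the whole quota is drawn in random mode.  Noise-labeled
    droplets never parent heterotypic doublets but may be drawn in random
    mode.
    """
    n_active = X.n_droplets
    if n_active < 2:
        raise ValueError("need at least two active droplets to simulate")
    n_sim = int(np.floor(SIM_FRACTION * n_active))
    if n_sim == 0:
        return SimulatedDoublets(
            sp.csr_matrix((0, X.n_peaks), dtype=X.values.dtype),
            np.empty((0, 2), dtype=int), np.empty(0, dtype=object))
    n_het = int(np.round(HET_FRACTION * n_sim)) if labels.n_clusters >= 2 else 0
    parents = np.empty((n_sim, 2), dtype=np.int64)
    mode = np.empty(n_sim, dtype=object)
    members = {c: np.flatnonzero(labels.labels == c) for c in labels.sizes}
    for i in range(n_het):
        ca, cb = sample_cluster_pair(labels, rng)
        parents[i, 0] = rng.choice(members[ca])
        parents[i, 1] = rng.choice(members[cb])
        mode[i] = "heterotypic"
    for i in range(n_het, n_sim):
        parents[i] = rng.choice(n_active, size=2, replace=False)
        mode[i] = "random"
    profiles = _combine(X.values[parents[:, 0]], X.values[parents[:, 1]], combine)
    return SimulatedDoublets(sp.csr_matrix(profiles), parents, mode)
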