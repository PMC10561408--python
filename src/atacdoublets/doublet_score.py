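"""Doublet-score aggregation over the KNN graph.

A node's doublet score is the similarity-weighted sum of its neighbors'
reference scores: neighbor distances are rescaled into similarities by a
reversed global min-max normalization,

    D' = (max(D) - D) / (max(D) - min(D)),

the reference vector L (1 for simulated doublets, a value in [0.1, 0.9] for
previously detected doublets, 0 otherwise) is gathered along the graph edges
into a matrix R, and

    S_i = sum_k D'_{i,k} * R_{i,k}.

A droplet surrounded by simulated doublets therefore scores high; one deep
inside a homogeneous singlet cluster scores near zero.
"""

from __future__ import annotations

import warnings

import numpy as np

from .knn_graph import NeighborGraph

__all__ = [
    "similarity_from_distance",
    "reference_matrix",
    "aggregate_scores",
    "scale_detected",
]

DETECTED_LO, DETECTED_HI = 0.1, 0.9


def similarity_from_distance(graph: NeighborGraph,
                             per_row: bool = False) -> np.ndarray:
    """Reversed min-max normalization of the distance matrix.

    Min and max are global scalars over the whole matrix by default;
    ``per_row=True`` normalizes each row independently (sensitivity
    analysis only).  A constant distance matrix maps to all ones.
    """
    D = np.asarray(graph.distances, dtype=np.float64)
    if not np.isfinite(D).all():
        raise ValueError("distances must be finite")
    if per_row:
        lo = D.min(axis=1, keepdims=True)
        hi = D.max(axis=1, keepdims=True)
        span = hi - lo
        flat = (span == 0).ravel()
        span[span == 0] = 1.0
        out = (hi - D) / span
        out[flat] = 1.0
        return out
    lo, hi = D.min(), D.max()
    if hi == lo:
        warnings.warn("constant distance matrix; all similarities set to 1")
        return np.ones_like(D)
    return (hi - D) / (hi - lo)


def reference_matrix(graph: NeighborGraph, L: np.ndarray) -> np.ndarray:
    """Gather reference scores of each node's neighbors: R[i, j] = L[nn_j(i)]."""
    L = np.asarray(L, dtype=np.float64)
    if graph.indices.min() < 0 or graph.indices.max() >= len(L):
        raise RuntimeError(
            "neighbor index outside the reference vector: node registry "
            "and KNN graph are out of sync")
    return L[graph.indices]


def aggregate_scores(similarities: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Row-wise sum of the element-wise product of similarity and reference."""
    similarities = np.asarray(similarities, dtype=np.float64)
    R = np.asarray(R, dtype=np.float64)
    if similarities.shape != R.shape:
        raise ValueError(
            f"shape mismatch: similarities {similarities.shape} vs R {R.shape}")
    return (similarities * R).sum(axis=1)


def scale_detected(scores: np.ndarray) -> np.ndarray:
    """Min-max rescale detected droplets' scores onto [0.1, 0.9].

    Distinguishes detected doublets from never-detected droplets (reference
    0) and simulated doublets (reference 1).  A single droplet, or equal
    scores, map to the midpoint 0.5.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("no detected droplets to rescale")
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        return np.full_like(scores, (DETECTED_LO + DETECTED_HI) / 2.0)
    return DETECTED_LO + (DETECTED_HI - DETECTED_LO) * (scores - lo) / (hi - lo)
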