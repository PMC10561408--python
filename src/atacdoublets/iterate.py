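"""Iterative-optimizing doublet detection.

Each iteration: cluster the still-active droplets, simulate artificial
doublets, re-normalize and embed the combined node set (active + detected +
simulated), build a KNN graph, aggregate doublet scores against the
reference vector L, fit a per-iteration detection threshold, flag new
doublets, and fold them back into L.  Detected droplets leave the
clustering/simulation pool but remain graph nodes with reference scores in
[0.1, 0.9].

The threshold comes from a two-distribution model of the score histogram:
active-droplet scores S_raw are modeled as the right half of a zero-mean
Gaussian (most droplets are singlets piling up near zero) and simulated-
doublet scores S_sim as a Gaussian; the threshold is the crossing point of
the two densities plus two standard deviations of S_sim.

The loop stops when the detected count reaches the expected doublet rate or
nothing new is detected — softened by an annealing rule that continues past
an early stop with a probability p that starts at 1 and decays faster the
more iterations have run.  Final scores are the per-droplet mean of S
across iterations, min-max scaled to [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import cluster_sim, doublet_score, knn_graph, matrix_io
from .matrix_io import CountMatrix

__all__ = [
    "DetectorConfig",
    "ThresholdFit",
    "IterationState",
    "DetectionResult",
    "fit_threshold",
    "run_iteration",
    "should_continue",
    "finalize",
    "call_doublets",
    "detect_doublets",
]


@dataclass
class DetectorConfig:
    """Tunable knobs of the detector; defaults follow the method's conventions."""

    expected_rate: float = 0.1          # user-supplied expected doublet rate
    min_peak_frac: float = 0.01         # peak-openness filter
    n_pcs: int = 30
    n_pcoa_coords: int = 30
    knn_dims: int = 2                   # UMAP dims fed to KNN in the PCA branch
    k_nn: int | None = None             # default round(0.5*sqrt(n_nodes)), >= 10
    eps: float = 0.1                    # DBSCAN eps on the 2-D embedding
    chi_threshold: float = 1.5
    strategy: str | None = None         # force "pca"/"pcoa"; None = adaptive
    combine: str = "sum"                # simulated-doublet combination rule
    max_iterations: int = 10
    tau: float = 3.0                    # annealing decay time-constant
    include_post_detection_scores: bool = True
    knn_method: str = "exact"


@dataclass
class ThresholdFit:
    """Half-normal / Gaussian density model of one iteration's scores."""

    sigma_raw: float
    mu_sim: float
    sigma_sim: float
    crossing: float
    s_th: float
    fallback: bool = False


@dataclass
class IterationState:
    """Bookkeeping across iterations of the detection loop."""

    n_raw: int
    expected_rate: float
    rng: np.random.Generator
    active: np.ndarray = field(default=None)
    detected: list = field(default_factory=list)     # in detection order
    detected_iteration: np.ndarray = field(default=None)
    L_raw: np.ndarray = field(default=None)          # reference scores, raw droplets
    score_history: list = field(default_factory=list)
    p: float = 1.0
    t: int = 0
    n_new_last: int = 0
    strategy: str | None = None
    chi_pca: float | None = None
    chi_pcoa: float | None = None
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.active is None:
            self.active = np.arange(self.n_raw)
        if self.L_raw is None:
            self.L_raw = np.zeros(self.n_raw)
        if self.detected_iteration is None:
            self.detected_iteration = np.zeros(self.n_raw, dtype=int)


@dataclass
class DetectionResult:
    """Final per-droplet doublet scores in [0, 1] and calls at a calling rate."""

    barcodes: np.ndarray
    final_scores: np.ndarray
    called_doublet: np.ndarray
    detected_iteration: np.ndarray
    n_iterations: int
    report: dict
    # raw per-iteration scores (n_iterations x n_used) over the QC-passing
    # droplets listed in used_indices; basis of the final averaged scores
    score_history: np.ndarray | None = None
    used_indices: np.ndarray | None = None


def _halfnorm_gauss_crossing(sigma_raw: float, mu_sim: float,
                             sigma_sim: float) -> float | None:
    """Root of half-normal(0, sigma_raw) = Normal(mu_sim, sigma_sim) in (0, mu_sim).

    The log-density equality is quadratic in x; among real roots inside the
    open interval the largest is returned (the decision boundary below the
    simulated-doublet bulk).  Returns None when no root lies in the interval
    (numeric bisection is tried as a fallback).
    """
    a = 1.0 / (2 * sigma_sim ** 2) - 1.0 / (2 * sigma_raw ** 2)
    b = -mu_sim / sigma_sim ** 2
    c = mu_sim ** 2 / (2 * sigma_sim ** 2) + math.log(2 * sigma_sim / sigma_raw)
    if a == 0:
        roots = [] if b == 0 else [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            roots = []
        else:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    inside = [r for r in roots if 0 < r < mu_sim]
    if inside:
        return max(inside)

    def f(x: float) -> float:
        return (-x ** 2 / (2 * sigma_raw ** 2) + (x - mu_sim) ** 2 /
                (2 * sigma_sim ** 2) + math.log(2 * sigma_sim / sigma_raw))

    xs = np.linspace(1e-12, mu_sim * (1 - 1e-12), 512)
    fs = np.array([f(x) for x in xs])
    sign_change = np.flatnonzero(np.diff(np.sign(fs)) != 0)
    if len(sign_change) == 0:
        return None
    from scipy.optimize import brentq

    i = sign_change[-1]
    return float(brentq(f, xs[i], xs[i + 1]))


def fit_threshold(s_raw: np.ndarray, s_sim: np.ndarray) -> ThresholdFit:
    """Fit the per-iteration detection threshold s_th.

    S_raw is fitted by a half-normal anchored at zero (MLE scale
    sqrt(mean(S_raw^2))), S_sim by a Gaussian (sample mean / std); the
    threshold is the density crossing point plus 2 * std(S_sim).  When the
    densities do not cross below the simulated mean — no separation — the
    threshold falls back above max(S_raw) so nothing is detected.
    """
    s_raw = np.asarray(s_raw, dtype=np.float64)
    s_sim = np.asarray(s_sim, dtype=np.float64)
    if len(s_raw) < 10 or len(s_sim) < 10:
        raise ValueError("need at least 10 raw and 10 simulated scores")
    sigma_raw = float(np.sqrt(np.mean(s_raw ** 2)))
    mu_sim = float(np.mean(s_sim))
    sigma_sim = float(np.std(s_sim, ddof=1))
    if sigma_sim == 0.0:
        # degenerate simulated scores: the crossing approaches mu_sim
        return ThresholdFit(sigma_raw, mu_sim, 0.0, mu_sim, mu_sim)
    if sigma_raw == 0.0:
        # all raw scores zero: any positive score is beyond the raw bulk
        return ThresholdFit(0.0, mu_sim, sigma_sim, 0.0, 2 * sigma_sim)
    crossing = _halfnorm_gauss_crossing(sigma_raw, mu_sim, sigma_sim)
    if crossing is None or mu_sim <= 0:
        s_th = float(s_raw.max()) + 1e-9
        return ThresholdFit(sigma_raw, mu_sim, sigma_sim, float("nan"),
                            s_th, fallback=True)
    return ThresholdFit(sigma_raw, mu_sim, sigma_sim, crossing,
                        crossing + 2 * sigma_sim)


def run_iteration(state: IterationState, X: CountMatrix,
                  config: DetectorConfig) -> IterationState:
    """One pass of the detection loop; mutates and returns ``state``.

    Node registry: raw droplets keep their original row order (active and
    detected interleaved), simulated doublets are appended after them.
    """
    state.t += 1
    t = state.t
    rng = state.rng
    seed_t = int(rng.integers(2 ** 31))
    active = state.active
    Xa = X.subset_droplets(active)
    # peaks can lose all their counts once detected droplets leave the pool;
    # drop them from the clustering view only (simulation keeps full columns)
    open_cols = Xa.values.sum(axis=0).A1 > 0
    Xa_cluster = Xa if open_cols.all() else CountMatrix(
        Xa.values[:, open_cols].tocsr(), Xa.barcodes, Xa.peaks[open_cols])

    Xa_norm = matrix_io.tfidf(Xa_cluster)
    emb_cluster = cluster_sim.embed_for_clustering(Xa_norm, config.n_pcs, seed_t)
    labels = cluster_sim.dbscan_cluster(emb_cluster, eps=config.eps)

    if state.strategy is None:
        if config.strategy is not None:
            state.strategy = config.strategy
        elif labels.n_clusters < 2:
            warnings.warn("single cluster on iteration 1; CHI undefined, "
                          "defaulting to the PCA strategy")
            state.strategy = "pca"
        else:
            strat, chi_pca, chi_pcoa = knn_graph.select_graph_strategy(
                emb_cluster, matrix_io.binarize(Xa_cluster).values, labels.labels,
                threshold=config.chi_threshold,
                n_coords=config.n_pcoa_coords, seed=seed_t)
            state.strategy = strat
            state.chi_pca, state.chi_pcoa = chi_pca, chi_pcoa

    sim = cluster_sim.simulate_doublets(Xa, labels, rng, combine=config.combine)
    if sim.n_sim < 10:
        state.n_new_last = 0
        state.log.append({"iteration": t, "aborted": "too few simulated doublets"})
        return state

    combined = sp.vstack([X.values, sim.profiles]).tocsr()
    n_nodes = combined.shape[0]
    if state.strategy == "pca":
        norm = matrix_io.tfidf(CountMatrix(
            combined,
            np.array([f"node{i}" for i in range(n_nodes)], dtype=object),
            X.peaks))
        emb = knn_graph.embed_pca(norm.values, config.n_pcs, seed_t,
                                  n_dims=config.knn_dims)
    else:
        binarized = combined.copy()
        binarized.data = np.ones_like(binarized.data)
        emb = knn_graph.embed_pcoa(binarized,
                                   n_coords=min(config.n_pcoa_coords, n_nodes - 1),
                                   seed=seed_t)

    k = config.k_nn or max(10, int(round(0.5 * math.sqrt(n_nodes))))
    graph = knn_graph.build_knn(emb, k, seed=seed_t, method=config.knn_method)

    L = np.concatenate([state.L_raw, np.ones(sim.n_sim)])
    Dp = doublet_score.similarity_from_distance(graph)
    R = doublet_score.reference_matrix(graph, L)
    S = doublet_score.aggregate_scores(Dp, R)
    s_raw_all, s_sim = S[:state.n_raw], S[state.n_raw:]
    s_active = s_raw_all[active]

    fit = fit_threshold(s_active, s_sim)
    new_mask = s_active > fit.s_th
    new_ids = active[new_mask]

    state.detected.extend(new_ids.tolist())
    state.detected_iteration[new_ids] = t
    state.active = active[~new_mask]
    state.n_new_last = len(new_ids)
    if state.detected:
        det = np.asarray(state.detected)
        state.L_raw[det] = doublet_score.scale_detected(s_raw_all[det])
    state.score_history.append(s_raw_all.copy())
    state.log.append({
        "iteration": t, "n_active": len(active), "n_sim": int(sim.n_sim),
        "n_clusters": labels.n_clusters, "s_th": float(fit.s_th),
        "crossing": float(fit.crossing), "sigma_raw": fit.sigma_raw,
        "mu_sim": fit.mu_sim, "sigma_sim": fit.sigma_sim,
        "n_new_detected": len(new_ids), "threshold_fallback": fit.fallback,
        "p": state.p,
    })
    return state


def should_continue(state: IterationState, config: DetectorConfig) -> bool:
    """Loop continuation rule with annealing.

    Stop when the detected count reaches floor(expected_rate * N) or the
    hard iteration cap; continue when the last iteration detected something;
    otherwise continue with probability p, which then decays by
    p <- p * exp(-t / tau) (compounding, so decay accelerates with t).
    """
    if state.t >= config.max_iterations:
        return False
    if len(state.detected) >= math.floor(state.expected_rate * state.n_raw):
        return False
    if state.n_new_last > 0:
        return True
    u = float(state.rng.random())
    cont = u < state.p
    state.p *= math.exp(-state.t / config.tau)
    return cont


def finalize(score_history: list[np.ndarray] | np.ndarray,
             mask: np.ndarray | None = None) -> np.ndarray:
    """Average scores across iterations, then min-max scale to [0, 1].

    ``mask`` (same shape as the stacked history) optionally excludes
    entries from the average, e.g. post-detection scores of detected
    droplets.
    """
    hist = np.asarray(score_history, dtype=np.float64)
    if hist.ndim != 2 or hist.shape[0] == 0:
        raise ValueError("need at least one completed iteration")
    if mask is None:
        means = hist.mean(axis=0)
    else:
        w = np.asarray(mask, dtype=np.float64)
        denom = w.sum(axis=0)
        denom[denom == 0] = 1.0
        means = (hist * w).sum(axis=0) / denom
    lo, hi = means.min(), means.max()
    if hi == lo:
        warnings.warn("all averaged scores equal; returning 0.5 everywhere")
        return np.full_like(means, 0.5)
    return (means - lo) / (hi - lo)


def call_doublets(final_scores: np.ndarray, calling_rate: float) -> np.ndarray:
    """Flag the top floor(calling_rate * N) droplets by final score.

    Ties at the cutoff are broken by lower droplet index (stable sort).
    """
    if not 0 < calling_rate < 1:
        raise ValueError("calling_rate must be in (0, 1)")
    scores = np.asarray(final_scores, dtype=np.float64)
    n_call = math.floor(calling_rate * len(scores))
    order = np.argsort(-scores, kind="stable")
    flags = np.zeros(len(scores), dtype=bool)
    flags[order[:n_call]] = True
    return flags


def detect_doublets(X: CountMatrix, expected_rate: float = 0.1,
                    seed: int = 0,
                    config: DetectorConfig | None = None) -> DetectionResult:
    """Run the full iterative detector on a raw count matrix.

    Droplets with zero total count (before or after peak filtering) are
    excluded from the computation and receive a final score of 0.
    """
    if config is None:
        config = DetectorConfig()
    config.expected_rate = expected_rate

    n_orig = X.n_droplets
    totals = X.values.sum(axis=1).A1
    usable = totals > 0
    Xq = X.subset_droplets(np.flatnonzero(usable))
    Xq = matrix_io.filter_peaks(Xq, config.min_peak_frac)
    totals2 = Xq.values.sum(axis=1).A1
    usable_idx = np.flatnonzero(usable)[totals2 > 0]
    Xq = X.subset_droplets(usable_idx)
    Xq = matrix_io.filter_peaks(Xq, config.min_peak_frac)

    state = IterationState(n_raw=Xq.n_droplets, expected_rate=expected_rate,
                           rng=np.random.default_rng(seed))
    while True:
        run_iteration(state, Xq, config)
        if not state.score_history and state.n_new_last == 0:
            raise RuntimeError("first iteration produced no scores")
        if not should_continue(state, config):
            break

    if config.include_post_detection_scores:
        mask = None
    else:
        hist = np.asarray(state.score_history)
        mask = np.ones_like(hist)
        for i in range(state.n_raw):
            it = state.detected_iteration[i]
            if it > 0:
                mask[it:, i] = 0.0
    final_q = finalize(state.score_history, mask)

    final_scores = np.zeros(n_orig)
    final_scores[usable_idx] = final_q
    detected_iteration = np.zeros(n_orig, dtype=int)
    detected_iteration[usable_idx] = state.detected_iteration
    called = call_doublets(final_scores, expected_rate)
    report = {
        "strategy": state.strategy,
        "chi_pca": state.chi_pca,
        "chi_pcoa": state.chi_pcoa,
        "expected_rate": expected_rate,
        "seed": seed,
        "n_droplets": n_orig,
        "n_droplets_used": int(Xq.n_droplets),
        "n_peaks_used": int(Xq.n_peaks),
        "n_detected": len(state.detected),
        "iterations": state.log,
    }
    return DetectionResult(X.barcodes, final_scores, called,
                           detected_iteration, state.t, report,
                           score_history=np.asarray(state.score_history),
                           used_indices=usable_idx)
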