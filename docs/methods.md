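# Methods

## Model and assumptions

`atacdoublets` is a simulation-based classifier: it assumes that a
heterotypic doublet's accessibility profile resembles the sum of two
profiles from different cell types, so that artificial doublets built by
summing real droplet pairs populate the same regions of the embedding as
true doublets. Scoring is a soft KNN vote — a droplet's score is the
similarity-weighted sum of its neighbors' reference scores — so the method
relies on the embedding placing doublets near simulated doublets rather
than on any parametric model of counts. Homotypic doublets, which sit
inside their parent cluster, are largely invisible to it by design.

The per-iteration detection threshold assumes the active-droplet score
distribution is dominated by singlets piling up near zero (modeled as the
right half of a zero-mean Gaussian with MLE scale σ̂ = √mean(S²)) while
simulated-doublet scores are approximately Gaussian. The threshold is the
density crossing point plus 2·std(S_sim). The crossing is the largest root
of the log-density quadratic inside (0, μ_sim), with numeric bisection as a
fallback; when no crossing exists (no separation) the threshold is placed
above max(S_raw) so the iteration detects nothing.

Degenerate cases: std(S_sim) = 0 treats the crossing as μ_sim (the limit of
the root as the Gaussian collapses); σ̂_raw = 0 (all raw scores zero) sets
the crossing to 0. A constant KNN distance matrix maps to all-ones
similarity. A single detected droplet, or all-equal detected scores,
rescale to the midpoint 0.5 of the [0.1, 0.9] reference band; the rescale
is applied to the *cumulative* detected set each iteration using their
current scores, which keeps the reference-vector partition
{0} ∪ [0.1, 0.9] ∪ {1} invariant.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `expected_rate` | 0.1 | user-supplied expected doublet fraction; stops the loop and sets the calling rate |
| `min_peak_frac` | 0.01 | drop peaks open in fewer than this fraction of droplets |
| `n_pcs` | 30 | SVD components before UMAP |
| `knn_dims` | 2 | UMAP dimensionality fed to the KNN graph (PCA branch) |
| `n_pcoa_coords` | 30 | PCoA axes used directly for the KNN graph (PCoA branch) |
| `k_nn` | round(0.5·√n_nodes), ≥ 10 | neighbors per node, the convention of simulation-based doublet detectors |
| `eps`, min_samples | 0.1, max(5, ⌊0.005·n⌋) | DBSCAN parameters on the 2-D embedding |
| `chi_threshold` | 1.5 | PCoA is chosen when CHI_PCoA/CHI_PCA ≥ 1.5 |
| `combine` | `sum` | parent-profile combination; counts add as reads mix (`max` gives the binary union) |
| `max_iterations` | 10 | hard cap on the loop |
| `tau` | 3.0 | annealing time constant, p ← p·exp(−t/τ) |

The embedding strategy is evaluated once, on the first iteration, and
frozen: the choice characterizes the dataset, not the iteration. If the
first clustering yields a single cluster the CHI ratio is undefined and the
PCA branch is used.

## Numerical choices

* TF-IDF uses the natural log and the (1 + P) numerator; the scale factor
  is irrelevant to the rank-based downstream use. It is recomputed each
  iteration on the concatenation of all raw droplets and the fresh
  simulated doublets, so simulated profiles are normalized consistently.
* The "PCA" stage is a truncated SVD of the sparse TF-IDF matrix (the LSI
  convention of scATAC analysis); dense centered PCA over 50k peaks would
  gain nothing for a UMAP input.
* UMAP runs with a fixed `random_state` (single-threaded, deterministic)
  and 200 optimization epochs — ample for the few-thousand-node embeddings
  built here.
* KNN search is exact brute force (chunked pairwise distances, stable
  argsort so ties break toward the lower node index). An approximate
  pynndescent index is available behind `knn_method="pynndescent"` and is
  tested to ≥ 0.95 recall against the exact graph.
* PCoA discards negative eigenvalues (Jaccard distances need not be
  Euclidean-embeddable) and fixes eigenvector signs by making the
  largest-magnitude loading positive. The Jaccard distance between two
  all-zero rows is defined as 0.
* Peaks that lose all their counts when detected droplets leave the active
  pool are dropped from the per-iteration clustering view only; the node
  registry and simulation keep the full peak set.
* Droplets with zero total count are excluded up front and receive a final
  score of 0.
* Scores of already-detected droplets keep being computed (they remain
  graph nodes) and are included in the final average by default;
  `include_post_detection_scores=False` averages each droplet only up to
  its detection iteration.

## Synthetic benchmark generator

`generate_singlets` partitions peaks into one block per cell type; a
droplet of type *t* draws independent Poisson counts with rate
depth·w_t[j], where w_t places `specificity` of its mass uniformly on the
type's block and the rest uniformly on all peaks. This equals a
multinomial over w_t with Poisson-distributed total depth and yields the
closed-form openness probability 1 − exp(−depth·w) per peak, which the
tests compare against realized sparsity. `plant_doublets` appends
⌊rate·n⌋ doublets whose parent types are drawn sequentially without
replacement with probability ∝ realized type proportions (real doublets
form more often between abundant types); profiles are parent sums,
optionally thinned binomially — a down-sampling rate r removes each read
with probability r, so doublets keep (1 − r) of their reads. The truth
generator's sum rule is deliberately the count-level "read mixing"
definition, independent of the detector's internal combination option.

The **standard benchmark** is 2,000 singlets over 50,000 peaks, five cell
types with proportions (0.35, 0.25, 0.2, 0.12, 0.08), depth 1,000,
specificity 0.8 (realized sparsity ≈ 0.98) and 20% planted doublets. The
down-sampling robustness sweep (rates 0, 0.2, 0.4 × three seeds) runs on a
regime-preserving scaled variant — 800 singlets, 20,000 peaks, depth
0.02·n_peaks — chosen so the per-peak Poisson rates, openness fractions and
sparsity are identical to the full benchmark at a fraction of the cost.

What the generator does **not** emulate: fragment-level structure (Tn5
insertion, duplicates), batch effects, GC/accessibility covariation,
continuous differentiation trajectories, or homotypic doublets. Passing
tests therefore demonstrate the machinery recovers planted heterotypic
doublets under realistic sparsity and imbalance, not performance on any
particular tissue.

## Known limitations

* Heterotypic doublets only; homotypic doublets require read-level
  statistics outside this package's scope.
* DBSCAN with eps = 0.1 can fragment a UMAP of a few hundred points into
  noise; the code falls back to a single cluster (random-mode simulation),
  which weakens, but does not break, detection on very small inputs.
* The annealing schedule and the crossing-point solver are this package's
  concrete choices for behavior that is qualitatively specified
  (continuation probability decaying faster with iteration count).
* With a calling rate above the true doublet fraction, precision is capped
  below 1 by construction; the ranked scores are the primary output.
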