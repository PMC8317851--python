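"""K-means gene grouping, patient subgrouping, and subsampled consensus clustering.

K-means itself is scikit-learn's (k-means++ seeding, ``n_init`` restarts);
cluster indices are canonicalised by lexicographically sorting the centroids
so that a permutation of the input rows cannot silently renumber clusters.
Consensus clustering follows the usual subsampled-stability scheme: the
consensus matrix entry (i, j) is the fraction of subsamples containing both
items in which they landed in the same cluster, and the best k is read off
the relative gain in area under the consensus CDF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .io import ExpressionMatrix
from .features import FeatureSet

#: relative delta-area gain below which adding a cluster is considered noise
DELTA_AREA_THRESHOLD = 0.1


@dataclass
class ClusterResult:
    item_ids: list[str]
    labels: np.ndarray  # integers in 1..k
    centroids: np.ndarray  # k x dims
    inertia: float

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def members(self, label: int) -> list[str]:
        return [i for i, l in zip(self.item_ids, self.labels) if l == label]


@dataclass
class ConsensusResult:
    k_values: list[int]
    consensus_matrices: dict[int, np.ndarray]
    cdf_curves: dict[int, tuple[np.ndarray, np.ndarray]]  # (grid, cdf)
    areas: dict[int, float]
    delta_area: dict[int, float]
    best_k: int


def _canonical_labels(raw: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Renumber clusters 1..k by lexicographic centroid order (permutation stable)."""
    order = np.lexsort(centroids.T[::-1])
    remap = np.empty(len(order), dtype=int)
    remap[order] = np.arange(1, len(order) + 1)
    return remap[raw], centroids[order]


def kmeans(X: np.ndarray, k: int, seed: int, n_init: int = 10,
           item_ids: list[str] | None = None) -> ClusterResult:
    """Lloyd's k-means (k-means++ seeding, best of ``n_init`` restarts)."""
    X = np.asarray(X, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of items {X.shape[0]}")
    if item_ids is None:
        item_ids = [str(i) for i in range(X.shape[0])]
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    labels, centroids = _canonical_labels(raw, km.cluster_centers_)
    return ClusterResult(list(item_ids), labels, centroids, float(km.inertia_))


def cluster_features(expr: ExpressionMatrix, scores, seed: int = 0) -> FeatureSet:
    """Split the selected genes into two k-means groups (rows = genes).

    Group 1 is the smaller cluster (ties broken by the cluster holding the
    lexicographically smallest gene ID), mirroring the convention that the
    favorable-subgroup marker set is the smaller one.
    """
    if expr.n_genes < 2:
        raise ValueError("need at least 2 genes to form two groups")
    res = kmeans(expr.values, k=2, seed=seed, item_ids=expr.gene_ids)
    sizes = {l: int((res.labels == l).sum()) for l in (1, 2)}
    first = {l: min(res.members(l)) for l in (1, 2)}
    small = min((1, 2), key=lambda l: (sizes[l], first[l]))
    group_of = {g: (1 if l == small else 2) for g, l in zip(res.item_ids, res.labels)}
    return FeatureSet(list(scores), group_of)


def consensus_cluster(
    X: np.ndarray,
    k_range=(2, 3, 4, 5),
    reps: int = 1000,
    subsample: float = 0.8,
    seed: int = 0,
    delta_threshold: float = DELTA_AREA_THRESHOLD,
) -> ConsensusResult:
    """Subsampled k-means consensus over a range of k; picks best_k by delta area.

    For each replicate a fraction ``subsample`` of items is drawn without
    replacement and clustered at every k; co-clustering counts are normalised
    by co-sampling counts.  best_k is the largest k whose relative gain in
    area under the consensus CDF still exceeds ``delta_threshold``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if reps < 1 or not (0 < subsample <= 1):
        raise ValueError("reps >= 1 and 0 < subsample <= 1 required")
    m = max(1, int(round(subsample * n)))
    k_range = sorted(k_range)
    if k_range[-1] > m:
        raise ValueError(f"k={k_range[-1]} exceeds subsample size {m}")
    rng = np.random.default_rng(seed)
    hits = {k: np.zeros((n, n)) for k in k_range}
    both = np.zeros((n, n))
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        both[np.ix_(idx, idx)] += 1
        sub_seed = int(rng.integers(2**31 - 1))
        for k in k_range:
            labels = kmeans(X[idx], k, seed=sub_seed).labels
            for lab in range(1, k + 1):
                members = idx[labels == lab]
                hits[k][np.ix_(members, members)] += 1

    consensus, cdfs, areas, delta = {}, {}, {}, {}
    grid = np.linspace(0.0, 1.0, 101)
    prev_area = None
    for k in k_range:
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(both > 0, hits[k] / np.where(both == 0, 1, both), 0.0)
        np.fill_diagonal(M, 1.0)
        consensus[k] = M
        off = M[np.triu_indices(n, 1)]
        cdf = np.array([(off <= g).mean() for g in grid])
        cdfs[k] = (grid, cdf)
        area = float(np.trapezoid(cdf, grid))
        areas[k] = area
        delta[k] = area if prev_area is None else (area - prev_area) / prev_area
        prev_area = area

    # walk upward until the relative gain first flattens; the largest k
    # before that point is the supported cluster count
    best_k = k_range[0]
    for k in k_range[1:]:
        if delta[k] <= delta_threshold:
            break
        best_k = k
    return ConsensusResult(list(k_range), consensus, cdfs, areas, delta, best_k)


def cluster_patients(
    expr: ExpressionMatrix,
    clin=None,
    k: int = 2,
    seed: int = 0,
) -> ClusterResult:
    """K-means on samples (rows = samples, dims = selected genes).

    When a clinical table is supplied, subgroups are renamed so that S1 (label
    1) is the cluster with the better observed survival — the higher
    Kaplan-Meier estimate at the median follow-up time.
    """
    if expr.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = expr.values.T
    if np.allclose(X, X[0]):
        warnings.warn("all samples identical: clustering is degenerate", stacklevel=2)
    res = kmeans(X, k=k, seed=seed, item_ids=expr.sample_ids)
    if clin is not None and k == 2:
        from .evaluate import km_survival_at

        clin = clin.subset(expr.sample_ids)
        t_med = float(np.median(clin.os_time))
        surv = {}
        for lab in (1, 2):
            mask = res.labels == lab
            surv[lab] = km_survival_at(clin.os_time[mask], clin.os_event[mask], t_med)
        if surv[2] > surv[1]:
            res.labels = 3 - res.labels
            res.centroids = res.centroids[::-1].copy()
    return res
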