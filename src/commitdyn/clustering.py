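"""Correlation-distance clustering and bootstrap cluster-stability assessment.

Cells (or gene temporal profiles) are clustered by k-means under the
1 − Pearson-correlation distance: assignment picks the centroid most
correlated with an item's profile, and the update step is the arithmetic
mean profile.  Robustness is judged cluster-wise: items are resampled with
replacement, reclustered, and each original cluster scored by its best
Jaccard similarity to any bootstrap cluster.  Clusters whose mean Jaccard
drifts toward 0.5 are considered unstable; a robust k is the largest k at
which every cluster stays stable.  Complete-linkage hierarchical clustering
under the same distance is provided for heat-map ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "ClusterAssignment",
    "StabilityReport",
    "kmeans_correlation",
    "bootstrap_jaccard_stability",
    "choose_robust_k",
    "hierarchical_complete_correlation",
    "jaccard",
]

STABLE_THRESHOLD = 0.75
UNSTABLE_THRESHOLD = 0.6


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # 1..k per item; 0 marks excluded zero-variance items
    centroids: np.ndarray  # k x n_features mean profiles
    k: int
    inertia: float  # sum of (1 - Pearson) to own centroid


@dataclass
class StabilityReport:
    mean_jaccard: np.ndarray  # per original cluster
    verdicts: list  # "stable" / "borderline" / "unstable"
    n_boot: int
    k: int


def _as_array(x) -> np.ndarray:
    if hasattr(x, "X"):
        x = x.X
    if sp.issparse(x):
        x = x.toarray()
    return np.asarray(x, float)


def _row_standardize(x: np.ndarray) -> np.ndarray:
    """Center and L2-normalize rows so dot products are Pearson correlations."""
    c = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(c, axis=1, keepdims=True)
    return c / norm


def _correlations(items_std: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    return items_std @ _row_standardize(centroids).T


def kmeans_correlation(
    x,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 100,
) -> ClusterAssignment:
    """Lloyd k-means with 1 − Pearson correlation as the distance.

    Items with zero variance cannot be correlated and are excluded with a
    warning (label 0).  Empty clusters are reseeded from the item farthest
    from its centroid.  The best of ``n_restarts`` seeded initialisations
    (by inertia) is returned.
    """
    X = _as_array(x)
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValueError("k must be between 1 and the number of items")
    var = X.var(axis=1)
    valid = var > 0
    if not valid.all():
        warnings.warn(
            f"excluding {int((~valid).sum())} zero-variance items from clustering",
            stacklevel=2,
        )
    Xv = X[valid]
    nv = Xv.shape[0]
    if k > nv:
        raise ValueError("k exceeds the number of non-degenerate items")
    Xstd = _row_standardize(Xv)

    rng = np.random.default_rng(seed)
    best_labels, best_centroids, best_inertia = None, None, np.inf
    for _ in range(max(1, n_restarts)):
        init = rng.choice(nv, size=k, replace=False)
        centroids = Xv[init].copy()
        labels = np.full(nv, -1)
        for _ in range(max_iter):
            corr = _correlations(Xstd, centroids)
            new_labels = corr.argmax(axis=1)
            # reseed empty clusters from the worst-fitting item
            for c in range(k):
                if not np.any(new_labels == c):
                    own_corr = corr[np.arange(nv), new_labels]
                    far = int(own_corr.argmin())
                    new_labels[far] = c
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            # keep the previous centroid if a cluster was emptied by reseeding
            centroids = np.vstack(
                [
                    Xv[labels == c].mean(axis=0) if np.any(labels == c) else centroids[c]
                    for c in range(k)
                ]
            )
        corr = _correlations(Xstd, centroids)
        inertia = float((1.0 - corr[np.arange(nv), labels]).sum())
        if inertia < best_inertia:
            best_labels, best_centroids, best_inertia = labels, centroids, inertia

    full = np.zeros(n, int)
    full[valid] = best_labels + 1
    return ClusterAssignment(
        labels=full, centroids=best_centroids, k=k, inertia=best_inertia
    )


def jaccard(a, b) -> float:
    """|A∩B| / |A∪B| over item-index sets."""
    a, b = set(a), set(b)
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def bootstrap_jaccard_stability(
    x,
    k: int,
    n_boot: int = 100,
    seed: int = 0,
    n_restarts: int = 5,
    reference: ClusterAssignment | None = None,
) -> StabilityReport:
    """Cluster-wise stability via bootstrap Jaccard similarities.

    For each bootstrap resample (items drawn with replacement) the data is
    reclustered at the same k, and every original cluster records its
    maximum Jaccard similarity — computed over the unique items present in
    the resample — to any bootstrap cluster.  An original cluster with no
    member in a resample scores 0 for that resample.
    """
    if k < 2:
        raise ValueError("stability assessment needs k >= 2")
    X = _as_array(x)
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = kmeans_correlation(
            X, k, n_restarts=max(n_restarts, 10), seed=int(rng.integers(2**31))
        )
    orig_members = [set(np.flatnonzero(reference.labels == c + 1)) for c in range(k)]

    sums = np.zeros(k)
    n = X.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        present = set(idx.tolist())
        boot = kmeans_correlation(
            X[idx], k, n_restarts=n_restarts, seed=int(rng.integers(2**31))
        )
        boot_members = [
            set(idx[boot.labels == c + 1].tolist()) for c in range(k)
        ]
        for c in range(k):
            restricted = orig_members[c] & present
            if not restricted:
                continue  # scores 0 for this resample
            sums[c] += max(jaccard(restricted, bm) for bm in boot_members)
    mean_j = sums / n_boot
    verdicts = [
        "stable" if j >= STABLE_THRESHOLD
        else ("unstable" if j < UNSTABLE_THRESHOLD else "borderline")
        for j in mean_j
    ]
    return StabilityReport(mean_jaccard=mean_j, verdicts=verdicts, n_boot=n_boot, k=k)


def choose_robust_k(
    x,
    k_range,
    n_boot: int = 100,
    seed: int = 0,
    threshold: float = STABLE_THRESHOLD,
    n_restarts: int = 5,
) -> int:
    """Largest k whose clusters are all stable (mean Jaccard ≥ threshold), else 1."""
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("empty k range")
    best = 1
    rng = np.random.default_rng(seed)
    for k in k_range:
        rep = bootstrap_jaccard_stability(
            x, k, n_boot=n_boot, seed=int(rng.integers(2**31)), n_restarts=n_restarts
        )
        if np.all(rep.mean_jaccard >= threshold):
            best = k
    return best


def hierarchical_complete_correlation(
    x, n_clusters: int | None = None, height: float | None = None
):
    """Complete-linkage agglomeration under the 1 − Pearson distance.

    Returns (linkage_matrix, flat_labels).  With neither ``n_clusters`` nor
    ``height`` given, the tree is cut at its tallest merge gap.
    """
    X = _as_array(x)
    if X.shape[0] < 2:
        raise ValueError("need at least two items")
    if np.any(X.var(axis=1) == 0):
        raise ValueError("zero-variance items have undefined correlation distance")
    d = pdist(X, metric="correlation")  # = 1 - Pearson
    Z = linkage(d, method="complete")
    if n_clusters is not None:
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    elif height is not None:
        labels = fcluster(Z, t=height, criterion="distance")
    else:
        merge_h = Z[:, 2]
        if len(merge_h) == 1:
            labels = fcluster(Z, t=2, criterion="maxclust")
        else:
            gaps = np.diff(merge_h)
            cut = (merge_h[gaps.argmax()] + merge_h[gaps.argmax() + 1]) / 2
            labels = fcluster(Z, t=cut, criterion="distance")
    return Z, labels
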