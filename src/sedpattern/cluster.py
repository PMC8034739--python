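"""Two-step cluster analysis: Ward agglomeration, then k-means refinement.

The dendrogram (Ward's method on squared Euclidean merge costs) picks
the number of clusters; cutting it at k seeds a deterministic Lloyd
k-means whose centroids start at the Ward cluster means.  No stochastic
initialization is used anywhere, so results are reproducible and
invariant to the seed of the surrounding pipeline.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "WardTree",
    "ClusterModel",
    "ward_linkage",
    "select_k",
    "cut_tree",
    "kmeans_refine",
    "match_clusters",
]

logger = logging.getLogger(__name__)


@dataclass
class WardTree:
    """Ward merge tree.

    ``merges[t]`` holds the two node ids merged at step *t* (leaves are
    0..n-1, internal nodes n, n+1, ...); ``heights[t]`` is the increase
    in total within-cluster sum of squares caused by that merge.  The
    merge-cost increments are non-decreasing and telescope to the total
    sum of squares of the data.
    """

    merges: np.ndarray  # (n-1, 2) int
    heights: np.ndarray  # (n-1,) within-SS increments
    n_leaves: int
    _linkage: np.ndarray = field(repr=False, default=None)

    def height_at(self, k: int) -> float:
        """Cost of the merge that reduces k+1 clusters to k."""
        if not 1 <= k <= self.n_leaves - 1:
            raise ValueError(f"k={k} outside [1, {self.n_leaves - 1}]")
        return float(self.heights[self.n_leaves - 1 - k])


def ward_linkage(X: np.ndarray) -> WardTree:
    """Agglomerative Ward clustering of the rows of *X*.

    Each step merges the pair of clusters whose union minimally
    increases the total within-cluster sum of squares (Lance-Williams
    recurrence on squared Euclidean distances).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least two observations")
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN")
    Z = linkage(X, method="ward")
    # scipy reports sqrt(2 * delta-SS) as the cophenetic distance
    heights = Z[:, 2] ** 2 / 2.0
    return WardTree(
        merges=Z[:, :2].astype(int),
        heights=heights,
        n_leaves=X.shape[0],
        _linkage=Z,
    )


def select_k(tree: WardTree, k_min: int = 2, k_max: int = 8) -> int:
    """Pick the number of clusters from the dendrogram.

    Returns the k in [k_min, k_max] maximizing the relative gap
    ``height(k-1) / height(k)`` between successive merge costs — the
    largest relative jump incurred when cutting from k to k-1 clusters,
    the numeric analogue of eyeballing the dendrogram.  Ties break to
    the smaller k.
    """
    if not 2 <= k_min <= k_max <= tree.n_leaves:
        raise ValueError(f"invalid k range [{k_min}, {k_max}] for n={tree.n_leaves}")
    if np.all(tree.heights <= 1e-12):
        warnings.warn("degenerate tree (all merge costs zero); returning k_min",
                      stacklevel=2)
        return k_min
    best_k, best_r = k_min, -np.inf
    for k in range(k_min, k_max + 1):
        denom = tree.height_at(k)
        if denom <= 0:
            continue
        r = tree.height_at(k - 1) / denom
        if r > best_r + 1e-12:
            best_k, best_r = k, r
    return best_k


def cut_tree(tree: WardTree, k: int) -> np.ndarray:
    """Labels (0..k-1) from cutting the dendrogram into k clusters."""
    return fcluster(tree._linkage, t=k, criterion="maxclust") - 1


@dataclass
class ClusterModel:
    """Converged two-step clustering result."""

    k: int
    centroids: np.ndarray  # k x p
    assignments: np.ndarray  # n
    within_ss: float
    iterations: int


def _within_ss(X, centroids, labels) -> float:
    return float(((X - centroids[labels]) ** 2).sum())


def kmeans_refine(X: np.ndarray, tree: WardTree, k: int, max_iter: int = 100) -> ClusterModel:
    """Deterministic Lloyd k-means seeded from the Ward partition.

    Initial centroids are the means of the k Ward clusters; iterations
    assign each point to its nearest centroid (ties to the lowest
    cluster index) and recompute means until assignments are unchanged
    or *max_iter* is reached.  A cluster emptied during iteration is
    re-seeded with the point farthest from its current centroid.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if k < 1 or n < k:
        raise ValueError(f"need 1 <= k <= n; got k={k}, n={n}")

    init = cut_tree(tree, k)
    centroids = np.stack([X[init == j].mean(axis=0) for j in range(k)])
    labels = init.copy()
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)  # argmin takes the lowest index on ties
        for j in range(k):
            members = new_labels == j
            if members.any():
                centroids[j] = X[members].mean(axis=0)
            else:
                far = int(((X - centroids[new_labels]) ** 2).sum(axis=1).argmax())
                logger.info("cluster %d emptied; re-seeded with point %d", j, far)
                centroids[j] = X[far]
                new_labels[far] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return ClusterModel(
        k=k,
        centroids=centroids,
        assignments=labels,
        within_ss=_within_ss(X, centroids, labels),
        iterations=it,
    )


def match_clusters(centroids: np.ndarray, archetype_means: np.ndarray) -> tuple:
    """Match clusters to reference archetypes.

    Returns the permutation ``perm`` minimizing the summed Euclidean
    distance between ``centroids[perm[a]]`` and ``archetype_means[a]``
    (exhaustive over the k! assignments), i.e. ``perm[a]`` is the
    cluster matched to archetype ``a``.
    """
    centroids = np.asarray(centroids, float)
    archetype_means = np.asarray(archetype_means, float)
    k = centroids.shape[0]
    if archetype_means.shape[0] != k:
        raise ValueError("centroid and archetype counts differ")
    if k > 8:
        raise ValueError("k > 8: use an assignment solver instead of enumeration")
    dist = np.linalg.norm(
        centroids[:, None, :] - archetype_means[None, :, :], axis=2
    )  # cluster x archetype
    best, best_cost = None, np.inf
    for perm in itertools.permutations(range(k)):
        cost = sum(dist[perm[a], a] for a in range(k))
        if cost < best_cost - 1e-15:
            best, best_cost = perm, cost
    return best
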