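"""Ward.D2 hierarchical clustering and resampling consensus clustering.

Both are implemented from first principles.  The agglomeration follows the
Ward.D2 convention: the Lance-Williams recurrence is applied to squared
Euclidean distances and merge heights are reported as the square root of
the minimal merge cost, which reproduces ``hclust(..., method="ward.D2")``
and SciPy's ``linkage(..., "ward")`` on Euclidean input.  Ties in the
minimal merge cost are broken by the smallest (row, column) index pair in
the current distance matrix, making every run deterministic for a given
input order.

The consensus estimator is the resampling co-clustering fraction: over
``reps`` subsamples of items (and optionally features), M[i, j] is the
number of repetitions in which i and j landed in the same cluster divided
by the number of repetitions in which both were sampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np

from .config import ClusterConfig

__all__ = [
    "WardTree",
    "ward_linkage",
    "ward_hclust",
    "ward_hclust_from_distance",
    "cut_tree",
    "ConsensusMatrix",
    "consensus_cluster",
]


@dataclass
class WardTree:
    """An agglomeration history in SciPy linkage layout.

    ``merges[step] = (id_a, id_b, height, size)`` where leaf ids are
    ``0..n-1`` and the cluster created at ``step`` has id ``n + step``.
    """

    n_items: int
    merges: np.ndarray  # (n-1, 4)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def _pairwise_sq_dists(points: np.ndarray) -> np.ndarray:
    sq = np.einsum("ij,ij->i", points, points)
    d2 = sq[:, None] + sq[None, :] - 2.0 * points @ points.T
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def ward_linkage(sq_dists: np.ndarray) -> WardTree:
    """Agglomerate from a squared-distance matrix with the Ward.D2 rule."""
    d2 = np.array(sq_dists, dtype=float)
    n = d2.shape[0]
    if d2.shape != (n, n):
        raise ValueError("squared-distance matrix must be square")
    if not np.all(np.isfinite(d2)):
        raise ValueError("non-finite distances")
    if n < 1:
        raise ValueError("need at least one item")
    merges = np.zeros((max(0, n - 1), 4))
    sizes = np.ones(n)
    cluster_id = np.arange(n)  # id of the cluster currently held in each slot
    active = np.ones(n, dtype=bool)
    work = d2.copy()
    big = np.inf
    work[~np.isfinite(work)] = big
    np.fill_diagonal(work, big)
    for step in range(n - 1):
        # smallest cost; np.argmin scans row-major, so ties resolve to the
        # smallest (i, j) slot pair
        flat = np.argmin(work)
        i, j = divmod(int(flat), n)
        if i > j:
            i, j = j, i
        cost = work[i, j]
        height = float(np.sqrt(cost))
        merges[step] = (cluster_id[i], cluster_id[j], height, sizes[i] + sizes[j])
        # Lance-Williams update for Ward on squared distances
        ni, nj = sizes[i], sizes[j]
        others = active.copy()
        others[i] = others[j] = False
        nk = sizes[others]
        dki = work[others, i]
        dkj = work[others, j]
        new = ((ni + nk) * dki + (nj + nk) * dkj - nk * cost) / (ni + nj + nk)
        work[others, i] = new
        work[i, others] = new
        sizes[i] = ni + nj
        cluster_id[i] = n + step
        active[j] = False
        work[j, :] = big
        work[:, j] = big
        work[i, i] = big
    return WardTree(n_items=n, merges=merges)


def cut_tree(tree: WardTree, k: int) -> np.ndarray:
    """Cut the hierarchy at k clusters.

    Labels are 0..k-1 in order of each cluster's smallest member index.
    """
    n = tree.n_items
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}]")
    parent = np.arange(2 * n - 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b, _, _ = tree.merges[step]
        new = n + step
        parent[find(int(a))] = new
        parent[find(int(b))] = new
    roots = np.array([find(i) for i in range(n)])
    labels = np.empty(n, dtype=int)
    next_label = 0
    seen: dict[int, int] = {}
    for i, r in enumerate(roots):
        if r not in seen:
            seen[r] = next_label
            next_label += 1
        labels[i] = seen[r]
    return labels


def ward_hclust(points: np.ndarray, k: int) -> np.ndarray:
    """Ward.D2 clustering of the rows of ``points`` into k clusters."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D item x feature matrix")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite values in points")
    if pts.shape[0] < k:
        raise ValueError(f"fewer items ({pts.shape[0]}) than clusters ({k})")
    tree = ward_linkage(_pairwise_sq_dists(pts))
    return cut_tree(tree, k)


def ward_hclust_from_distance(dists: np.ndarray, k: int) -> np.ndarray:
    """Ward.D2 clustering from a precomputed distance matrix."""
    d = np.asarray(dists, dtype=float)
    if d.shape[0] < k:
        raise ValueError("fewer items than clusters")
    tree = ward_linkage(d**2)
    return cut_tree(tree, k)


@dataclass
class ConsensusMatrix:
    """Pairwise co-clustering fractions with their co-sampling tallies."""

    item_ids: list
    M: np.ndarray
    sampling_counts: np.ndarray

    def __post_init__(self) -> None:
        M = self.M
        if not np.allclose(M, M.T):
            raise ValueError("consensus matrix must be symmetric")
        if M.size and (M.min() < -1e-12 or M.max() > 1 + 1e-12):
            raise ValueError("consensus entries outside [0, 1]")
        sampled = np.diag(self.sampling_counts) > 0
        if not np.allclose(np.diag(M)[sampled], 1.0):
            raise ValueError("diagonal must be 1 for every sampled item")


def consensus_cluster(
    values: np.ndarray,
    config: ClusterConfig,
    item_ids: list | None = None,
) -> tuple[ConsensusMatrix, np.ndarray]:
    """Monti-style consensus clustering of the rows of ``values``.

    Each repetition subsamples ``ceil(p_item * n)`` rows and
    ``ceil(p_feature * m)`` columns without replacement, clusters the
    subsample with Ward.D2 at ``config.k``, and tallies co-clustering.
    Final labels come from Ward.D2 on ``1 - M`` treated as a distance.
    Identical seeds give identical output.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("values must be 2-D (items x features)")
    n, m = X.shape
    if m < 2:
        raise ValueError("need at least 2 features")
    k = config.k
    n_sub = ceil(config.p_item * n)
    m_sub = ceil(config.p_feature * m)
    if n_sub < k:
        raise ValueError(
            f"p_item * n_items = {n_sub} is smaller than k = {k}"
        )
    if n < k:
        raise ValueError("fewer items than clusters")
    rng = np.random.default_rng(config.seed)
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(config.reps):
        items = np.sort(rng.choice(n, size=n_sub, replace=False))
        feats = (
            np.arange(m)
            if m_sub == m
            else np.sort(rng.choice(m, size=m_sub, replace=False))
        )
        labels = ward_hclust(X[np.ix_(items, feats)], k)
        ind = np.zeros((n,), dtype=bool)
        ind[items] = True
        sampled[np.ix_(items, items)] += 1.0
        for c in range(k):
            members = items[labels == c]
            together[np.ix_(members, members)] += 1.0
    never = sampled == 0
    if never.any():
        warnings.warn(
            f"{int(never.sum())} item pairs were never co-sampled; their "
            "consensus is reported as 0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(never, 0.0, together / np.maximum(sampled, 1e-300))
    M = (M + M.T) / 2.0
    cm = ConsensusMatrix(
        item_ids=list(item_ids) if item_ids is not None else list(range(n)),
        M=M,
        sampling_counts=sampled,
    )
    final = ward_hclust_from_distance(1.0 - M, k)
    return cm, final
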