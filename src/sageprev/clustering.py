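"""Expression-profile clustering: k-means with most-distant seeding, and
average-linkage hierarchical clustering under correlation distance.

Both analyses follow the EPCLUST-style procedure used for SAGE expression
matrices.  The metric is d = 1 - Pearson r (range [0, 2]); a zero-variance
profile is assigned distance 1 to everything (uncorrelated convention).
K-means is seeded deterministically: the first seed is the profile farthest
from the grand mean, each further seed maximizes its average distance to
the seeds already chosen.  The number of clusters can be chosen
automatically as the smallest k whose partition isolates a solitary
library.  Hierarchical clustering is classic UPGMA agglomeration on the
same metric; every tie breaks to the lowest original row index, so results
are fully reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

__all__ = [
    "ClusteringConfig",
    "ClusterAssignment",
    "Dendrogram",
    "correlation_distance",
    "pairwise_correlation_distance",
    "kmeans",
    "choose_k",
    "hierarchical",
]


@dataclass(frozen=True)
class ClusteringConfig:
    k: int
    init_rule: str = "most_distant_average"
    max_iter: int = 100
    seed: int = 0
    distance: str = "correlation"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.init_rule != "most_distant_average":
            raise ValueError(f"unknown init rule {self.init_rule!r}")
        if self.distance != "correlation":
            raise ValueError(f"unknown distance {self.distance!r}")


@dataclass
class ClusterAssignment:
    labels: dict[int, int]  # row index -> cluster index
    sizes: dict[int, int]
    singleton_clusters: list[int]
    n_iter: int = 0

    def members(self, cluster: int) -> list[int]:
        return [i for i, c in self.labels.items() if c == cluster]


@dataclass
class Dendrogram:
    """Binary merge tree in scipy linkage convention.

    ``merges[s] = (a, b, height, size)`` merges clusters ``a`` and ``b``
    (leaves are 0..n-1, the cluster formed at step s gets id n+s) at the
    given average-linkage height.
    """

    n_leaves: int
    merges: list[tuple[int, int, float, int]]
    labels: list[str] = field(default_factory=list)

    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def cophenetic_matrix(self) -> np.ndarray:
        """Leaf x leaf matrix of merge heights."""
        n = self.n_leaves
        members = {i: [i] for i in range(n)}
        coph = np.zeros((n, n))
        for step, (a, b, h, _) in enumerate(self.merges):
            for i in members[a]:
                for j in members[b]:
                    coph[i, j] = coph[j, i] = h
            members[n + step] = members.pop(a) + members.pop(b)
        return coph

    def to_newick(self) -> str:
        """Ultrametric newick string: each leaf sits at depth height/2 from
        its cluster's merge, so cophenetic distances are preserved."""
        labels = self.labels or [str(i) for i in range(self.n_leaves)]
        depth = {i: 0.0 for i in range(self.n_leaves)}
        text = {i: labels[i] for i in range(self.n_leaves)}
        for step, (a, b, h, _) in enumerate(self.merges):
            node = self.n_leaves + step
            half = h / 2.0
            la = max(half - depth[a], 0.0)
            lb = max(half - depth[b], 0.0)
            text[node] = f"({text[a]}:{la:.6g},{text[b]}:{lb:.6g})"
            depth[node] = half
        root = self.n_leaves + len(self.merges) - 1
        newick = text[root] + ";"
        # round-trip through dendropy validates the string
        dendropy.Tree.get(data=newick, schema="newick")
        return newick


def correlation_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """d = 1 - Pearson r, in [0, 2].

    A zero-variance vector has undefined correlation; the distance is then
    defined as 1 (uncorrelated) and a warning is emitted.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size < 2:
        raise ValueError("vectors must be 1-D, equal length >= 2")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0.0 or ny == 0.0:
        warnings.warn("zero-variance vector: correlation distance set to 1", stacklevel=2)
        return 1.0
    r = float(xc @ yc / (nx * ny))
    return 1.0 - max(-1.0, min(1.0, r))


def _standardized(rows: np.ndarray) -> np.ndarray:
    """Center and L2-normalize rows; zero-variance rows become zero vectors,
    which makes their correlation with anything 0 (distance 1)."""
    centred = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norms > 0, centred / norms, 0.0)
    return z


def pairwise_correlation_distance(rows: np.ndarray) -> np.ndarray:
    """Symmetric n x n matrix of correlation distances between rows."""
    z = _standardized(np.asarray(rows, dtype=float))
    d = 1.0 - np.clip(z @ z.T, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def _distances_to_profiles(rows: np.ndarray, profiles: np.ndarray) -> np.ndarray:
    zr = _standardized(rows)
    zp = _standardized(profiles)
    return 1.0 - np.clip(zr @ zp.T, -1.0, 1.0)


def _most_distant_seeds(rows: np.ndarray, k: int) -> list[int]:
    """Deterministic seeding: farthest row from the grand mean profile, then
    repeatedly the row maximizing its average distance to chosen seeds."""
    grand_mean = rows.mean(axis=0, keepdims=True)
    d0 = _distances_to_profiles(rows, grand_mean)[:, 0]
    seeds = [int(np.argmax(d0))]  # argmax takes the lowest index on ties
    pairwise = pairwise_correlation_distance(rows)
    while len(seeds) < k:
        avg = pairwise[:, seeds].mean(axis=1)
        avg[seeds] = -np.inf
        seeds.append(int(np.argmax(avg)))
    return seeds


def kmeans(rows: np.ndarray, config: ClusteringConfig) -> ClusterAssignment:
    """Deterministic k-means under correlation distance.

    Rows are the items to cluster (libraries, after transposing a
    genes-as-rows matrix).  Cluster centres are arithmetic mean profiles;
    assignment ties break to the lowest cluster index, so identical inputs
    always give identical partitions.
    """
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    if config.k > n:
        raise ValueError(f"k={config.k} exceeds number of rows {n}")
    seeds = _most_distant_seeds(rows, config.k)
    centroids = rows[seeds].copy()
    labels = np.full(n, -1, dtype=int)
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        dist = _distances_to_profiles(rows, centroids)
        new_labels = np.argmin(dist, axis=1)  # lowest index wins ties
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(config.k):
            mask = labels == c
            if mask.any():
                centroids[c] = rows[mask].mean(axis=0)
            # an emptied cluster keeps its previous centre
    sizes = {c: int((labels == c).sum()) for c in range(config.k)}
    return ClusterAssignment(
        labels={i: int(labels[i]) for i in range(n)},
        sizes=sizes,
        singleton_clusters=[c for c, s in sizes.items() if s == 1],
        n_iter=n_iter,
    )


def kmeans_objective(rows: np.ndarray, labels: dict[int, int]) -> float:
    """Sum over items of correlation distance to their cluster's mean profile."""
    rows = np.asarray(rows, dtype=float)
    total = 0.0
    for c in sorted(set(labels.values())):
        idx = [i for i, ci in labels.items() if ci == c]
        centroid = rows[idx].mean(axis=0, keepdims=True)
        total += float(_distances_to_profiles(rows[idx], centroid)[:, 0].sum())
    return total


def choose_k(
    rows: np.ndarray, config: ClusteringConfig, k_max: int
) -> tuple[int, ClusterAssignment]:
    """Smallest k in 1..k_max whose partition contains a singleton cluster.

    Falls back to k_max (with a warning) when no partition isolates a
    solitary row.
    """
    rows = np.asarray(rows, dtype=float)
    if k_max > rows.shape[0]:
        raise ValueError("k_max exceeds number of rows")
    last = None
    for k in range(1, k_max + 1):
        cfg = ClusteringConfig(
            k=k,
            init_rule=config.init_rule,
            max_iter=config.max_iter,
            seed=config.seed,
            distance=config.distance,
        )
        last = kmeans(rows, cfg)
        if last.singleton_clusters:
            return k, last
    warnings.warn(f"no k <= {k_max} produced a singleton cluster", stacklevel=2)
    assert last is not None
    return k_max, last


def hierarchical(rows: np.ndarray, labels: Sequence[str] | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration under correlation distance.

    At each step the pair of clusters with the smallest mean pairwise leaf
    distance merges; the merge height is that mean.  Ties break to the pair
    whose smallest original row indices are lowest.
    """
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to cluster")
    base = pairwise_correlation_distance(rows)

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    # exact sums of leaf-pair distances between clusters; averages derive from them
    sums: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            sums[(i, j)] = float(base[i, j])
    rep = {i: i for i in range(n)}  # smallest original leaf index per cluster

    merges: list[tuple[int, int, float, int]] = []
    active = set(range(n))
    for step in range(n - 1):
        best = None
        for i, j in sums:
            avg = sums[(i, j)] / (len(members[i]) * len(members[j]))
            key = (avg, min(rep[i], rep[j]), max(rep[i], rep[j]))
            if best is None or key < best[0]:
                best = (key, i, j)
        (avg, _, _), a, b = best
        new = n + step
        members[new] = members[a] + members[b]
        rep[new] = min(rep[a], rep[b])
        for other in active - {a, b}:
            s = sums.pop((min(a, other), max(a, other))) + sums.pop(
                (min(b, other), max(b, other))
            )
            sums[(min(new, other), max(new, other))] = s
        sums.pop((min(a, b), max(a, b)))
        active -= {a, b}
        active.add(new)
        merges.append((a, b, avg, len(members[new])))
        del members[a], members[b]

    return Dendrogram(
        n_leaves=n,
        merges=merges,
        labels=list(labels) if labels is not None else [],
    )
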