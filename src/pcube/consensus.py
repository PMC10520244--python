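"""Consensus (ensemble) clustering of the encoded cohort.

Evidence-accumulation construction: run a collection of base clusterings
(K-means restarts and agglomerative runs with several linkages) across a
range of cluster counts, accumulate the n x n co-association matrix
M[i, j] = fraction of base partitions placing i and j together, and cut an
average-linkage tree built on the distance 1 - M.

The number of consensus clusters K is chosen by a consensus-fit stability
score: for each candidate K the partition is compared with M through the
mean absolute deviation between M and the partition's block indicator over
off-diagonal pairs (0 = every pair either always or never co-clusters,
exactly as the partition says; lower = more stable).  Ties prefer smaller
K.  The classic PAC (proportion of ambiguous clustering: off-diagonal
entries strictly inside (u1, u2)) is computed alongside as a global
ambiguity diagnostic.

Clusters smaller than ``min_cluster_size`` are merged into the cluster
with the highest mean co-association, so every subgroup stays large enough
to support a survival-model fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import AgglomerativeClustering, KMeans

from .preprocess import FeatureMatrix


class ConsensusError(ValueError):
    pass


DEFAULT_LINKAGES = ("ward", "average", "complete")


@dataclass(frozen=True)
class BasePartitionSet:
    """Label vectors from every base run, with per-run provenance."""

    partitions: np.ndarray  # (R, n) integer labels
    provenance: tuple[dict[str, Any], ...]

    def __post_init__(self) -> None:
        parts = np.asarray(self.partitions)
        if parts.ndim != 2:
            raise ConsensusError("partitions must be an (R, n) array")
        if parts.shape[0] != len(self.provenance):
            raise ConsensusError("one provenance record required per partition")
        object.__setattr__(self, "partitions", parts)

    @property
    def n_runs(self) -> int:
        return self.partitions.shape[0]

    @property
    def n(self) -> int:
        return self.partitions.shape[1]


def default_min_cluster_size(n: int) -> int:
    """max(30, 2% of n): small enough to find minorities, large enough to fit."""
    return max(30, int(np.ceil(0.02 * n)))


def run_base_clusterings(
    X: FeatureMatrix | np.ndarray,
    k_range: Sequence[int] = range(2, 9),
    n_kmeans_restarts: int = 10,
    linkages: Sequence[str] = DEFAULT_LINKAGES,
    seed: int = 0,
) -> BasePartitionSet:
    """K-means restarts plus one agglomerative run per linkage, for each k."""
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    n = values.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ConsensusError("empty k_range")
    if max(ks) > n:
        raise ConsensusError(f"k={max(ks)} exceeds the number of rows ({n})")
    rng = np.random.default_rng(seed)
    parts: list[np.ndarray] = []
    prov: list[dict[str, Any]] = []
    for k in ks:
        for r in range(n_kmeans_restarts):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            km = KMeans(n_clusters=k, n_init=1, random_state=sub_seed)
            parts.append(km.fit_predict(values))
            prov.append({"algorithm": "kmeans", "k": k, "seed": sub_seed, "restart": r})
        for link in linkages:
            agg = AgglomerativeClustering(n_clusters=k, linkage=link, metric="euclidean")
            parts.append(agg.fit_predict(values))
            prov.append({"algorithm": "agglomerative", "k": k, "linkage": link})
    return BasePartitionSet(partitions=np.asarray(parts), provenance=tuple(prov))


def build_coassociation(parts: BasePartitionSet) -> np.ndarray:
    """M[i, j] = fraction of base partitions with label_i == label_j."""
    if parts.n_runs < 1:
        raise ConsensusError("need at least one base partition")
    n = parts.n
    M = np.zeros((n, n))
    for labels in parts.partitions:
        M += labels[:, None] == labels[None, :]
    M /= parts.n_runs
    return M


@dataclass
class ConsensusResult:
    coassoc: np.ndarray
    chosen_K: int
    labels: np.ndarray  # 1-based, values 1..chosen_K
    stability: dict[int, float]  # candidate K -> consensus-fit score (lower = better)
    pac: float  # global proportion of ambiguous clustering
    min_cluster_size: int
    degenerate: bool = False

    def cluster_sizes(self) -> dict[int, int]:
        lab, cnt = np.unique(self.labels, return_counts=True)
        return {int(a): int(b) for a, b in zip(lab, cnt)}


def _cut_tree(M: np.ndarray, K: int) -> np.ndarray:
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="average")
    return fcluster(Z, t=K, criterion="maxclust")


def _consensus_fit(M: np.ndarray, labels: np.ndarray) -> float:
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(M.shape[0], k=1)
    return float(np.mean(np.abs(M[iu] - same[iu])))


def _merge_small(M: np.ndarray, labels: np.ndarray, min_size: int) -> np.ndarray:
    labels = labels.copy()
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        if len(uniq) <= 1 or counts.min() >= min_size:
            break
        small = uniq[np.argmin(counts)]
        members = labels == small
        best, best_score = None, -np.inf
        for other in uniq:
            if other == small:
                continue
            score = float(M[np.ix_(members, labels == other)].mean())
            if score > best_score:
                best, best_score = other, score
        labels[members] = best
    # relabel consecutively 1..K, ordered by first appearance
    out = np.zeros_like(labels)
    nxt = 1
    seen: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = nxt
            nxt += 1
        out[i] = seen[lab]
    return out


def consensus_partition(
    parts: BasePartitionSet,
    k_range: Sequence[int] = range(2, 9),
    pac_bounds: tuple[float, float] = (0.1, 0.9),
    min_cluster_size: int | None = None,
    force_K: int | None = None,
) -> ConsensusResult:
    """Select K and extract the consensus partition from an ensemble.

    ``force_K`` pins the cut level (stability scores are still computed);
    used when refitting under a fixed subgroup count.
    """
    M = build_coassociation(parts)
    return consensus_partition_from_matrix(M, k_range, pac_bounds, min_cluster_size, force_K)


def consensus_partition_from_matrix(
    M: np.ndarray,
    k_range: Sequence[int] = range(2, 9),
    pac_bounds: tuple[float, float] = (0.1, 0.9),
    min_cluster_size: int | None = None,
    force_K: int | None = None,
) -> ConsensusResult:
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if M.shape != (n, n) or np.any(M < -1e-12) or np.any(M > 1 + 1e-12):
        raise ConsensusError("invalid co-association matrix")
    ks = sorted(set(int(k) for k in k_range if 1 <= int(k) <= n))
    if not ks:
        raise ConsensusError("empty or infeasible k_range")
    if min_cluster_size is None:
        min_cluster_size = 1
    u1, u2 = pac_bounds
    iu = np.triu_indices(n, k=1)
    off = M[iu]
    pac = float(np.mean((off > u1) & (off < u2))) if off.size else 0.0

    degenerate = bool(off.size and np.all(off >= u2))
    stability: dict[int, float] = {}
    cuts: dict[int, np.ndarray] = {}
    for K in sorted(set(ks) | ({int(force_K)} if force_K is not None else set())):
        cut = _cut_tree(M, K)
        cuts[K] = cut
        stability[K] = _consensus_fit(M, cut)
    if force_K is not None:
        chosen = int(force_K)
    elif degenerate:
        warnings.warn("co-association matrix shows no structure; choosing smallest K")
        chosen = ks[0]
    else:
        best = min(stability.values())
        chosen = min(K for K, s in stability.items() if s <= best + 1e-15)
    labels = _merge_small(M, cuts[chosen], min_cluster_size)
    return ConsensusResult(
        coassoc=M,
        chosen_K=int(labels.max()),
        labels=labels,
        stability=stability,
        pac=pac,
        min_cluster_size=min_cluster_size,
        degenerate=degenerate,
    )


def cluster_centroids(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(unique labels, centroid matrix) of an encoded training set."""
    X = np.asarray(X, dtype=float)
    uniq = np.unique(labels)
    cents = np.vstack([X[labels == lab].mean(axis=0) for lab in uniq])
    return uniq, cents


def assign_to_cluster(
    x_new: np.ndarray,
    result: ConsensusResult,
    X_train: np.ndarray,
) -> np.ndarray:
    """Nearest-centroid assignment for new encoded rows (ties -> lower label)."""
    uniq, cents = cluster_centroids(X_train, result.labels)
    return assign_to_centroids(x_new, uniq, cents)


def assign_to_centroids(x_new: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(x_new, dtype=float))
    if X.shape[1] != centroids.shape[1]:
        raise ConsensusError(
            f"dimension mismatch: {X.shape[1]} features vs centroids with {centroids.shape[1]}"
        )
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    # argmin returns the first (lowest-label) minimizer, which is the tie rule
    order = np.argsort(labels)
    d2 = d2[:, order]
    idx = np.argmin(d2, axis=1)
    out = np.asarray(labels)[order][idx]
    return out if out.size > 1 else out
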