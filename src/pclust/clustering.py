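"""Crisp clustering backends over a similarity matrix.

Three algorithms partition the database: single-linkage agglomerative
clustering, k-means (careful seeding + Lloyd iterations), and connected
components of the thresholded similarity graph. For the two geometric
methods each profile is embedded as its row of S/100, i.e. a point in
N-dimensional space whose coordinates are its (rescaled) similarities to
every database profile; connected components works on S directly as an
edge-weighted graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _csgraph_components
from scipy.spatial.distance import pdist
from sklearn.cluster import kmeans_plusplus

from pclust.matrix import SimilarityMatrix

METHOD_SINGLE_LINKAGE = "single_linkage"
METHOD_KMEANS = "kmeans"
METHOD_CONNECTED_COMPONENTS = "connected_components"


@dataclass(frozen=True)
class Partition:
    """A crisp clustering: disjoint non-empty clusters covering all IDs.

    Cluster order is deterministic: clusters are sorted by their
    smallest member ID, and members within a cluster are sorted.
    """

    clusters: tuple[frozenset[str], ...]
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if not c:
                raise ValueError("empty cluster in partition")
            if seen & c:
                raise ValueError(f"clusters are not disjoint: {sorted(seen & c)}")
            seen |= c

    @property
    def n_profiles(self) -> int:
        return sum(len(c) for c in self.clusters)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "method": self.method,
            "params": self.params,
            "clusters": [sorted(c) for c in self.clusters],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Partition":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        payload = json.loads(text)
        return _make_partition(
            [set(c) for c in payload["clusters"]], payload["method"], payload["params"]
        )

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("profile_id\tcluster_index\n")
            for ci, cluster in enumerate(self.clusters):
                for pid in sorted(cluster):
                    fh.write(f"{pid}\t{ci}\n")


@dataclass(frozen=True)
class PartitionStats:
    """Cluster-size distribution summary."""

    n_clusters: int
    n_singletons: int
    n_nonsingleton: int
    max_size: int
    histogram: dict[int, int]

    def as_text(self) -> str:
        """Histogram as a size-vs-frequency table."""
        lines = ["size\tfrequency"]
        for size in sorted(self.histogram):
            lines.append(f"{size}\t{self.histogram[size]}")
        return "\n".join(lines)


def _make_partition(groups: Sequence[set[str]], method: str, params: Mapping) -> Partition:
    ordered = sorted((frozenset(g) for g in groups if g), key=lambda c: min(c))
    return Partition(clusters=tuple(ordered), method=method, params=dict(params))


def _groups_from_labels(ids: Sequence[str], labels: np.ndarray) -> list[set[str]]:
    groups: dict[int, set[str]] = {}
    for pid, lab in zip(ids, labels):
        groups.setdefault(int(lab), set()).add(pid)
    return list(groups.values())


def cluster_connected_components(S: SimilarityMatrix, psi: float) -> Partition:
    """Connected components of the graph whose edges score at least *psi*.

    Two profiles share a cluster iff a path of pairwise similarities
    >= psi connects them (the diagonal is ignored). psi is on the
    0-100 percent scale.
    """
    if not (0.0 <= psi <= 100.0):
        raise ValueError(f"edge-weight threshold psi must lie in [0, 100], got {psi}")
    adj = S.values >= psi
    np.fill_diagonal(adj, False)
    n_comp, labels = _csgraph_components(csr_matrix(adj), directed=False)
    groups = _groups_from_labels(S.ids, labels)
    return _make_partition(groups, METHOD_CONNECTED_COMPONENTS, {"psi": psi})


def cluster_single_linkage(
    S: SimilarityMatrix, zeta: float, criterion: str = "distance"
) -> Partition:
    """Single-linkage agglomeration of the row-vector embedding, cut at *zeta*.

    Rows of S/100 are N-dimensional samples; Euclidean distances feed
    the agglomeration and the dendrogram is cut at *zeta* under either
    the ``distance`` criterion (merge-height cut) or the
    ``inconsistency`` coefficient criterion.
    """
    if zeta <= 0:
        raise ValueError(f"cutoff zeta must be positive, got {zeta}")
    if criterion not in ("distance", "inconsistency"):
        raise ValueError(f"criterion must be 'distance' or 'inconsistency', got {criterion!r}")
    X = S.values / 100.0
    if S.n == 1:
        return _make_partition([set(S.ids)], METHOD_SINGLE_LINKAGE,
                               {"zeta": zeta, "criterion": criterion})
    Z = linkage(pdist(X, metric="euclidean"), method="single")
    scipy_criterion = "distance" if criterion == "distance" else "inconsistent"
    labels = fcluster(Z, t=zeta, criterion=scipy_criterion)
    groups = _groups_from_labels(S.ids, labels)
    return _make_partition(groups, METHOD_SINGLE_LINKAGE,
                           {"zeta": zeta, "criterion": criterion})


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int, tol: float):
    """Lloyd iterations; returns (labels, centers, inertia trace).

    Assignment ties break to the lowest centroid index (argmin). A
    centroid that loses all points keeps its previous position; its
    empty cluster is dropped downstream.
    """
    k = centers.shape[0]
    inertia_trace: list[float] = []
    labels = np.zeros(len(X), dtype=int)
    for _ in range(max_iter):
        # squared Euclidean distances to each centroid
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        inertia_trace.append(float(d2[np.arange(len(X)), labels].sum()))
        new_centers = centers.copy()
        for c in range(k):
            mask = labels == c
            if mask.any():
                new_centers[c] = X[mask].mean(axis=0)
        shift = float(np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max())
        centers = new_centers
        if shift <= tol:
            break
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    inertia_trace.append(float(d2[np.arange(len(X)), labels].sum()))
    return labels, centers, inertia_trace


def cluster_kmeans(
    S: SimilarityMatrix,
    k: int,
    seed: int,
    *,
    n_restarts: int = 1,
    max_iter: int = 300,
    tol: float = 1e-6,
    return_trace: bool = False,
):
    """k-means on the row-vector embedding with careful (k-means++) seeding.

    Squared Euclidean distance in the S/100 row space; Lloyd iterations
    run to convergence (centroid movement <= *tol*) or *max_iter*.
    Clusters that end up empty are dropped from the partition. With
    ``n_restarts`` > 1 the restart with the lowest within-cluster sum
    of squares wins (seeds derived from *seed*).
    """
    if not (1 <= k <= S.n):
        raise ValueError(f"k must lie in [1, {S.n}], got {k}")
    X = S.values / 100.0
    best = None
    rng = np.random.RandomState(seed)
    restart_seeds = [seed] + [int(rng.randint(0, 2**31 - 1)) for _ in range(n_restarts - 1)]
    for rs in restart_seeds:
        centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=rs)
        labels, centers, trace = _lloyd(X, centers, max_iter=max_iter, tol=tol)
        if best is None or trace[-1] < best[2][-1]:
            best = (labels, centers, trace)
    labels, _, trace = best
    groups = _groups_from_labels(S.ids, labels)  # empty clusters never materialize as groups
    part = _make_partition(groups, METHOD_KMEANS,
                           {"k": k, "seed": seed, "n_restarts": n_restarts})
    if return_trace:
        return part, trace
    return part


def partition_stats(p: Partition) -> PartitionStats:
    """Cluster count, singleton count, maximum size and size histogram."""
    sizes = [len(c) for c in p.clusters]
    histogram: dict[int, int] = {}
    for s in sizes:
        histogram[s] = histogram.get(s, 0) + 1
    n_singletons = histogram.get(1, 0)
    return PartitionStats(
        n_clusters=len(sizes),
        n_singletons=n_singletons,
        n_nonsingleton=len(sizes) - n_singletons,
        max_size=max(sizes),
        histogram=histogram,
    )
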