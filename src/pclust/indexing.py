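"""Representative selection and clustered-index assembly.

A cluster's representative is the member whose within-cluster similarity
sum is maximal — the profile most homologous to everything else in its
cluster, playing the role a medoid plays in distance space. Queries are
matched against the representatives first, so singleton clusters (which
get no representative in crisp mode) must be scanned exhaustively; the
overlapping re-assignment removes that cost by giving every profile at
least one represented cluster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from pclust.clustering import Partition
from pclust.matrix import SimilarityMatrix


@dataclass(frozen=True)
class ClusteredIndex:
    """Clusters, their representatives, and the unrepresented singleton pool.

    In crisp mode (``overlapped=False``) clusters are disjoint, each
    size->=2 cluster has a representative, and the sole members of
    singleton clusters sit in ``singleton_pool`` (the M profiles scanned
    exhaustively at query time). After the overlapping re-assignment,
    clusters may share members and the pool is empty (M = 0).
    """

    clusters: tuple[frozenset[str], ...]
    representatives: tuple[str, ...]
    singleton_pool: frozenset[str]
    overlapped: bool
    source_params: dict

    def __post_init__(self) -> None:
        if len(self.clusters) != len(self.representatives):
            raise ValueError("one representative per cluster required")
        for ci, (cluster, rep) in enumerate(zip(self.clusters, self.representatives)):
            if not cluster:
                raise ValueError(f"cluster {ci} is empty")
            if rep not in cluster:
                raise ValueError(f"representative {rep!r} is not a member of cluster {ci}")
        if self.overlapped and self.singleton_pool:
            raise ValueError("an overlapped index cannot have a singleton pool")

    @property
    def k(self) -> int:
        """Number of represented clusters (K)."""
        return len(self.clusters)

    @property
    def m(self) -> int:
        """Number of unrepresented singleton profiles (M)."""
        return len(self.singleton_pool)

    @property
    def all_ids(self) -> frozenset[str]:
        out: set[str] = set(self.singleton_pool)
        for c in self.clusters:
            out |= c
        return frozenset(out)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "source_params": self.source_params,
            "overlapped": self.overlapped,
            "representatives": {str(i): r for i, r in enumerate(self.representatives)},
            "clusters": {str(i): sorted(c) for i, c in enumerate(self.clusters)},
            "singleton_pool": sorted(self.singleton_pool),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ClusteredIndex":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        payload = json.loads(text)
        order = sorted(payload["clusters"], key=int)
        return cls(
            clusters=tuple(frozenset(payload["clusters"][i]) for i in order),
            representatives=tuple(payload["representatives"][i] for i in order),
            singleton_pool=frozenset(payload["singleton_pool"]),
            overlapped=bool(payload["overlapped"]),
            source_params=dict(payload["source_params"]),
        )


def select_representative(cluster: Iterable[str], S: SimilarityMatrix) -> str:
    """The cluster member with the maximum within-cluster similarity sum.

    Ties break to the lexicographically smallest ID. The self-similarity
    diagonal contributes the same constant to every member's sum, so the
    argmax is unaffected by it.
    """
    members = sorted(cluster)
    if not members:
        raise ValueError("cannot select a representative of an empty cluster")
    sub = S.submatrix(members)  # raises KeyError for members missing from S
    sums = sub.sum(axis=1)
    return members[int(np.argmax(sums))]  # argmax takes first = smallest ID on ties


def build_crisp_index(p: Partition, S: SimilarityMatrix) -> ClusteredIndex:
    """Assemble the crisp index: representatives for size->=2 clusters,
    singleton members pooled for exhaustive scanning."""
    clusters: list[frozenset[str]] = []
    reps: list[str] = []
    pool: set[str] = set()
    for cluster in p.clusters:
        if len(cluster) == 1:
            pool |= cluster
        else:
            clusters.append(frozenset(cluster))
            reps.append(select_representative(cluster, S))
    return ClusteredIndex(
        clusters=tuple(clusters),
        representatives=tuple(reps),
        singleton_pool=frozenset(pool),
        overlapped=False,
        source_params={"method": p.method, **p.params},
    )


def membership_for_profile(scores_vs_reps: np.ndarray) -> np.ndarray:
    """Boolean mask of clusters a profile joins under the self-regulated rule.

    The profile joins every cluster whose representative scores it at or
    above the mean of its scores against all K representatives. The max
    of a finite vector is >= its mean, so at least one entry is True.
    """
    theta = scores_vs_reps.mean()
    return scores_vs_reps >= theta


def overlap_assign(
    index: ClusteredIndex,
    S: SimilarityMatrix,
    *,
    extra_profiles: Mapping[str, np.ndarray] | None = None,
) -> ClusteredIndex:
    """Re-assign every database profile to clusters by the self-regulated rule.

    For each profile, its mean score against the K representatives is a
    per-profile threshold; the profile joins every cluster whose
    representative meets it. Crisp members of represented clusters are
    retained (the re-assignment only adds memberships), former singleton
    clusters dissolve, and the resulting index has an empty pool (M = 0).
    Representatives are unchanged.

    *extra_profiles* maps a new profile ID (not in S) to its score vector
    against the representatives, in cluster order — the incremental path
    for growing a database without re-clustering.
    """
    if index.overlapped:
        raise ValueError("index is already overlapped")
    if index.k == 0:
        raise ValueError(
            "cannot overlap an index with no represented clusters; use sequential search"
        )
    rep_rows = np.stack([S.row(r) for r in index.representatives])  # K x N
    new_clusters = [set(c) for c in index.clusters]
    for j, pid in enumerate(S.ids):
        mask = membership_for_profile(rep_rows[:, j])
        for ci in np.flatnonzero(mask):
            new_clusters[ci].add(pid)
    if extra_profiles:
        for pid, scores in extra_profiles.items():
            scores = np.asarray(scores, dtype=float)
            if scores.shape != (index.k,):
                raise ValueError(
                    f"score vector for {pid!r} must have length K={index.k}"
                )
            for ci in np.flatnonzero(membership_for_profile(scores)):
                new_clusters[ci].add(pid)
    return ClusteredIndex(
        clusters=tuple(frozenset(c) for c in new_clusters),
        representatives=index.representatives,
        singleton_pool=frozenset(),
        overlapped=True,
        source_params=dict(index.source_params),
    )
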