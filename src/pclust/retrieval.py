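"""Staged query answering against a clustered index.

A query is scored against the K cluster representatives, then against
every member of the best representative's cluster, then against the
unrepresented singleton pool. The exact number of pairwise comparisons
per query is NC = K + size(chosen cluster) + M, versus N for exhaustive
sequential search; the hit set is always a subset of the sequential one
because only a slice of the database is ever scored.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from pclust.indexing import ClusteredIndex
from pclust.matrix import ProfileDB, SimilarityMatrix

logger = logging.getLogger(__name__)

#: Default match threshold: scores at or above 95 on the 0-100 scale are
#: treated as near-certain homology.
DEFAULT_PHI = 95.0


@dataclass(frozen=True)
class Hit:
    target: str
    score: float


@dataclass(frozen=True)
class NCBreakdown:
    """Exact comparison counts per retrieval stage."""

    k_comparisons: int
    cluster_comparisons: int
    m_comparisons: int

    @property
    def total(self) -> int:
        return self.k_comparisons + self.cluster_comparisons + self.m_comparisons


@dataclass(frozen=True)
class QueryResult:
    query_id: str
    hits: tuple[Hit, ...]
    best_representative: int | None
    nc: NCBreakdown
    elapsed: float

    @property
    def hit_ids(self) -> frozenset[str]:
        return frozenset(h.target for h in self.hits)


class MatrixQueryScorer:
    """Query scorer backed by precomputed query-vs-database score vectors.

    A query is referenced by ID; its vector maps every database profile
    ID to a 0-100 score. ``from_matrix`` builds the leave-one-in variant
    where every database profile doubles as a query and its matrix row
    supplies the scores. Each requested target counts as exactly one
    pairwise comparison.
    """

    def __init__(self, vectors: Mapping[str, Mapping[str, float]]):
        self._vectors = vectors
        self._comparisons = 0

    @classmethod
    def from_matrix(cls, S: SimilarityMatrix) -> "MatrixQueryScorer":
        vectors = {
            qid: dict(zip(S.ids, S.values[i])) for i, qid in enumerate(S.ids)
        }
        return cls(vectors)

    @classmethod
    def from_arrays(cls, S: SimilarityMatrix,
                    queries: Mapping[str, np.ndarray]) -> "MatrixQueryScorer":
        """Wrap query score vectors given as arrays aligned to S.ids."""
        vectors = {qid: dict(zip(S.ids, np.asarray(v, dtype=float)))
                   for qid, v in queries.items()}
        return cls(vectors)

    @property
    def comparisons(self) -> int:
        return self._comparisons

    def __call__(self, query: str, target_ids: Sequence[str]) -> dict[str, float]:
        vec = self._vectors[query]
        self._comparisons += len(target_ids)
        return {t: float(vec[t]) for t in target_ids}


def _rank_hits(scores: Mapping[str, float], phi: float) -> tuple[Hit, ...]:
    hits = [Hit(t, s) for t, s in scores.items() if s >= phi]
    hits.sort(key=lambda h: (-h.score, h.target))
    return tuple(hits)


def retrieve(
    query,
    scorer,
    index: ClusteredIndex,
    phi: float = DEFAULT_PHI,
    *,
    query_id: str | None = None,
    top_n_clusters: int = 1,
) -> QueryResult:
    """Answer one query through the staged representative-first search.

    Stage 1 scores the query against all K representatives and picks the
    best (ties: lowest cluster index). Stage 2 scores it against every
    member of that cluster; stage 3 against the singleton pool. Hits are
    the stage-2/3 targets scoring at or above *phi*, deduplicated keeping
    the maximum score.

    ``top_n_clusters`` > 1 widens stage 2 to the clusters of the n
    best-scoring representatives — an extension beyond the validated
    single-cluster design; ``best_representative`` reports the top one.
    """
    if index.k == 0 and not index.singleton_pool:
        raise ValueError("empty index: no represented clusters and no singleton pool")
    qid = query_id if query_id is not None else str(query)
    t0 = time.perf_counter()

    k_comp = cluster_comp = m_comp = 0
    merged: dict[str, float] = {}
    best_ci: int | None = None

    if top_n_clusters < 1:
        raise ValueError("top_n_clusters must be >= 1")
    if index.k > 0:
        before = scorer.comparisons
        rep_scores = scorer(query, list(index.representatives))
        k_comp = scorer.comparisons - before
        # rank representatives; ties break to the lowest cluster index
        ranked = sorted(
            range(index.k),
            key=lambda ci: (-rep_scores[index.representatives[ci]], ci),
        )
        best_ci = ranked[0]
        chosen = ranked[:top_n_clusters]
        members = sorted(set().union(*(index.clusters[ci] for ci in chosen)))
        before = scorer.comparisons
        member_scores = scorer(query, members)
        cluster_comp = scorer.comparisons - before
        for t, s in member_scores.items():
            merged[t] = max(merged.get(t, -1.0), s)

    if index.singleton_pool:
        pool = sorted(index.singleton_pool)
        before = scorer.comparisons
        pool_scores = scorer(query, pool)
        m_comp = scorer.comparisons - before
        for t, s in pool_scores.items():
            merged[t] = max(merged.get(t, -1.0), s)

    elapsed = time.perf_counter() - t0
    return QueryResult(
        query_id=qid,
        hits=_rank_hits(merged, phi),
        best_representative=best_ci,
        nc=NCBreakdown(k_comp, cluster_comp, m_comp),
        elapsed=elapsed,
    )


def sequential_search(
    query,
    scorer,
    db: ProfileDB | Sequence[str],
    phi: float = DEFAULT_PHI,
    *,
    query_id: str | None = None,
) -> QueryResult:
    """Exhaustive baseline: score the query against all N database profiles."""
    ids = list(db.ids) if hasattr(db, "ids") else list(db)
    if not ids:
        raise ValueError("empty database")
    qid = query_id if query_id is not None else str(query)
    t0 = time.perf_counter()
    before = scorer.comparisons
    scores = scorer(query, ids)
    n_comp = scorer.comparisons - before
    elapsed = time.perf_counter() - t0
    return QueryResult(
        query_id=qid,
        hits=_rank_hits(scores, phi),
        best_representative=None,
        nc=NCBreakdown(0, n_comp, 0),
        elapsed=elapsed,
    )


def batch_retrieve(
    queries: Sequence,
    scorer,
    index: ClusteredIndex,
    phi: float = DEFAULT_PHI,
    *,
    failures: list | None = None,
) -> list[QueryResult]:
    """Staged retrieval for a batch; failing queries are logged and skipped.

    Results come back in input order. If *failures* is given, tuples of
    (query, exception) are appended to it.
    """
    if len(queries) == 0:
        raise ValueError("batch must contain at least one query")
    results: list[QueryResult] = []
    for q in queries:
        try:
            results.append(retrieve(q, scorer, index, phi))
        except Exception as exc:  # per-query failures are not fatal
            logger.warning("query %r failed: %s", q, exc)
            if failures is not None:
                failures.append((q, exc))
    return results


def results_to_tsv(results: Sequence[QueryResult]) -> str:
    """One row per hit: query_id, target_id, score, rank."""
    lines = ["query_id\ttarget_id\tscore\trank"]
    for r in results:
        for rank, h in enumerate(r.hits, start=1):
            lines.append(f"{r.query_id}\t{h.target}\t{h.score:.6g}\t{rank}")
    return "\n".join(lines)
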