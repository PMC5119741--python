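"""Recall and search-cost reduction of clustered retrieval vs sequential.

Recall treats every sequential hit as relevant (precision is trivially 1
because clustered retrieval only ever scores a subset of the database).
Reduction in time compares summed wall-clock per query; the hardware-free
proxy compares summed pairwise-comparison counts against the T*N cost of
sequential search over T queries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from pclust.retrieval import QueryResult


class SubsetViolationError(ValueError):
    """A proposed hit set was not a subset of its sequential baseline.

    This cannot happen when both searches use the same scorer and
    threshold; it indicates an inconsistent scorer.
    """


@dataclass(frozen=True)
class EvalReport:
    """Batch evaluation summary over T queries."""

    per_query_recall: tuple[float, ...]
    batch_recall: float
    rt_wallclock: float
    rt_comparisons: float
    T: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "T": self.T,
            "batch_recall": self.batch_recall,
            "rt_wallclock": self.rt_wallclock,
            "rt_comparisons": self.rt_comparisons,
            "per_query_recall": list(self.per_query_recall),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def recall_single(proposed: Iterable[str], baseline: Iterable[str]) -> float:
    """|baseline ∩ proposed| / |baseline|; 1.0 when the baseline is empty
    (no relevant matches existed to be missed)."""
    b = set(baseline)
    if not b:
        return 1.0
    return len(b & set(proposed)) / len(b)


def recall_batch(
    proposed_sets: Sequence[Iterable[str]],
    baseline_sets: Sequence[Iterable[str]],
) -> float:
    """Total proposed hits over total baseline hits across the batch.

    Valid as a recall because each proposed set is a subset of its
    baseline; a violation is diagnosed as a scorer inconsistency.
    Queries with empty baselines contribute zero to both sums.
    """
    if len(proposed_sets) != len(baseline_sets):
        raise ValueError("proposed and baseline lists must be pairwise aligned")
    num = den = 0
    for i, (p, b) in enumerate(zip(proposed_sets, baseline_sets)):
        p, b = set(p), set(b)
        if not p <= b:
            raise SubsetViolationError(
                f"query {i}: proposed hits {sorted(p - b)} missing from the "
                "sequential baseline; scorer is inconsistent between runs"
            )
        num += len(p)
        den += len(b)
    if den == 0:
        return 1.0
    return num / den


def reduction_in_time(alphas: Sequence[float], alpha_primes: Sequence[float]) -> float:
    """1 - (summed clustered-search time / summed sequential time)."""
    if len(alphas) != len(alpha_primes):
        raise ValueError("time lists must be pairwise aligned")
    total_baseline = sum(alpha_primes)
    if total_baseline <= 0:
        raise ValueError("sequential baseline time sums to zero; ratio undefined")
    return 1.0 - sum(alphas) / total_baseline


def comparison_reduction(nc_totals: Sequence[int], n_db: int, t: int) -> float:
    """1 - (summed comparison counts / t*N): the hardware-independent
    analogue of the wall-clock reduction."""
    if t <= 0 or n_db <= 0:
        raise ValueError("database size and query count must be positive")
    if len(nc_totals) != t:
        raise ValueError(f"expected {t} per-query comparison counts, got {len(nc_totals)}")
    return 1.0 - sum(nc_totals) / (t * n_db)


def evaluate_batch(
    proposed: Sequence[QueryResult],
    baseline: Sequence[QueryResult],
    n_db: int,
) -> EvalReport:
    """Full report from aligned clustered and sequential result lists."""
    if len(proposed) != len(baseline):
        raise ValueError("result lists must be pairwise aligned")
    per_query = tuple(
        recall_single(p.hit_ids, b.hit_ids) for p, b in zip(proposed, baseline)
    )
    batch = recall_batch([p.hit_ids for p in proposed], [b.hit_ids for b in baseline])
    rt = reduction_in_time([p.elapsed for p in proposed], [b.elapsed for b in baseline])
    rc = comparison_reduction([p.nc.total for p in proposed], n_db, len(proposed))
    return EvalReport(
        per_query_recall=per_query,
        batch_recall=batch,
        rt_wallclock=rt,
        rt_comparisons=rc,
        T=len(proposed),
    )
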