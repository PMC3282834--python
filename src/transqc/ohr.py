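"""Ortholog hit ratios: how much of its best-hit ortholog a transcript covers.

The ratio for a query is the number of subject (protein) residues covered by
the merged union of its HSP intervals against its top-hit subject, divided by
that subject's length. A ratio of 1 suggests the transcript was assembled to
its full length; threshold summaries use strict inequality ("over 50%" means
ratio > 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .dedup import DedupParams, select_top_hit
from .io import BlastHit

__all__ = [
    "RatioRecord",
    "merge_intervals",
    "covered_positions",
    "ortholog_hit_ratio",
    "compute_ratios",
    "ratio_fractions",
    "ratio_histogram",
]


@dataclass(frozen=True)
class RatioRecord:
    query_id: str
    subject_id: str
    covered_aa: int
    subject_length_aa: int

    @property
    def ratio(self) -> float:
        return self.covered_aa / self.subject_length_aa


def merge_intervals(
    intervals: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Merge inclusive integer intervals into a minimal disjoint sorted set.

    Abutting intervals ([1,50],[51,60]) merge, since they cover contiguous
    integer positions.
    """
    ivals = sorted(intervals)
    for start, end in ivals:
        if start > end:
            raise ValueError(f"interval ({start},{end}) has start > end")
    if not ivals:
        return []
    merged = [ivals[0]]
    for start, end in ivals[1:]:
        last_start, last_end = merged[-1]
        if start <= last_end + 1:
            merged[-1] = (last_start, max(last_end, end))
        else:
            merged.append((start, end))
    return merged


def covered_positions(intervals: Iterable[tuple[int, int]]) -> int:
    """Number of distinct integer positions covered by the intervals."""
    return sum(e - s + 1 for s, e in merge_intervals(intervals))


def ortholog_hit_ratio(
    hits: Sequence[BlastHit], subject_length_aa: int
) -> RatioRecord:
    """Ratio record for one query-subject pair from its HSPs.

    All hits must share one query and one subject; coverage is the merged
    union of the subject-coordinate intervals.
    """
    if not hits:
        raise ValueError("no hits supplied")
    queries = {h.query_id for h in hits}
    subjects = {h.subject_id for h in hits}
    if len(queries) > 1 or len(subjects) > 1:
        raise ValueError("hits must share a single query-subject pair")
    if subject_length_aa <= 0:
        raise ValueError(f"invalid subject length for {hits[0].subject_id!r}")
    covered = covered_positions(h.subject_interval for h in hits)
    return RatioRecord(
        query_id=hits[0].query_id,
        subject_id=hits[0].subject_id,
        covered_aa=covered,
        subject_length_aa=subject_length_aa,
    )


def compute_ratios(
    hits: Iterable[BlastHit],
    subject_lengths: Mapping[str, int],
    params: DedupParams = DedupParams(),
) -> list[RatioRecord]:
    """Per-query ratio records using each query's top-hit subject.

    For each query the top hit is selected under ``params``; coverage then
    pools every passing HSP of that query against that subject. Subjects
    missing from ``subject_lengths`` raise ``KeyError`` naming the subject.
    """
    by_query: dict[str, list[BlastHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    records = []
    for query_id in sorted(by_query):
        qhits = by_query[query_id]
        top = select_top_hit(qhits, params, query_length=0)
        if top is None:
            continue
        if top.subject_id not in subject_lengths:
            raise KeyError(f"no length for subject {top.subject_id!r}")
        pair = [
            h
            for h in qhits
            if h.subject_id == top.subject_id and h.evalue <= params.evalue_cutoff
        ]
        records.append(ortholog_hit_ratio(pair, subject_lengths[top.subject_id]))
    return records


def ratio_fractions(
    ratios: Sequence[float], thresholds: Sequence[float] = (0.5, 0.8)
) -> dict[float, float]:
    """Fraction of ratios strictly above each threshold."""
    if not ratios:
        raise ValueError("empty ratio list")
    return {
        t: sum(1 for r in ratios if r > t) / len(ratios) for t in thresholds
    }


def ratio_histogram(ratios: Sequence[float], bins: int = 10) -> list[int]:
    """Counts in ``bins`` equal right-closed bins on (0, 1].

    Ratios of exactly zero (possible only for degenerate zero-coverage
    records, which the pipeline does not produce) fall into the first bin.
    """
    counts = [0] * bins
    for r in ratios:
        if not 0 <= r <= 1:
            raise ValueError(f"ratio {r} outside [0,1]")
        idx = 0 if r == 0 else int(-(-r * bins // 1)) - 1  # ceil(r*bins) - 1
        counts[idx] += 1
    return counts
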