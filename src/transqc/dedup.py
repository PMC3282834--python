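"""Unique-transcript estimation from BLAST top-hit HSP overlaps.

De novo assemblies fragment transcripts, so several assembly products can hit
the same reference protein. Products sharing a top BLAST hit whose HSP
subject intervals do *not* overlap (by more than a small threshold, default
14 aa — just above the assembler's 40-nt minimum overlap, ~13.3 aa) are
treated as fragments of one transcript; products whose intervals *do* overlap
are putative splice isoforms or paralogues. The unique-transcript count is
then the number of distinct top-hit subjects.

Overlap is measured in subject (protein) coordinates: fragments of one
transcript align to different regions of the same protein, so only
alignment-shared residues are meaningful. Classification is pairwise against
the group representative (the longest member), which is deterministic and
order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import BlastHit

__all__ = [
    "DedupParams",
    "TopHit",
    "UniqueTranscript",
    "select_top_hit",
    "build_top_hits",
    "interval_overlap_aa",
    "dedupe",
    "count_unique",
]


@dataclass(frozen=True)
class DedupParams:
    """Deduplication thresholds.

    overlap_threshold_aa: members sharing strictly more than this many
        subject residues with the representative are isoforms/paralogues.
    evalue_cutoff: hits with E-value above this never enter the analysis.
    """

    overlap_threshold_aa: int = 14
    evalue_cutoff: float = 1e-10

    def __post_init__(self) -> None:
        if self.overlap_threshold_aa < 0:
            raise ValueError("overlap_threshold_aa must be >= 0")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")


@dataclass(frozen=True)
class TopHit:
    """The selected top BLAST hit of one query."""

    query_id: str
    query_length: int
    subject_id: str
    subject_interval: tuple[int, int]
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class UniqueTranscript:
    """A deduplicated transcript group for one top-hit subject."""

    subject_id: str
    representative: str
    representative_length: int
    fragments: tuple[str, ...]
    isoforms_or_paralogues: tuple[str, ...]

    @property
    def members(self) -> tuple[str, ...]:
        return (self.representative,) + self.fragments + self.isoforms_or_paralogues


def select_top_hit(
    hits_for_query: Sequence[BlastHit],
    params: DedupParams,
    query_length: int,
) -> TopHit | None:
    """Select the top hit of one query, or None if nothing passes the cutoff.

    The winning row has minimum E-value, ties broken by maximum bitscore and
    then input order. When the winning query-subject pair has several HSPs,
    the reported subject interval is that of the highest-bitscore HSP.
    """
    passing = [h for h in hits_for_query if h.evalue <= params.evalue_cutoff]
    if not passing:
        return None
    queries = {h.query_id for h in hits_for_query}
    if len(queries) > 1:
        raise ValueError(f"hits from multiple queries: {sorted(queries)}")
    best = min(enumerate(passing), key=lambda ih: (ih[1].evalue, -ih[1].bitscore, ih[0]))[1]
    pair_hsps = [h for h in passing if h.subject_id == best.subject_id]
    interval_hsp = min(enumerate(pair_hsps), key=lambda ih: (-ih[1].bitscore, ih[0]))[1]
    return TopHit(
        query_id=best.query_id,
        query_length=query_length,
        subject_id=best.subject_id,
        subject_interval=interval_hsp.subject_interval,
        evalue=best.evalue,
        bitscore=best.bitscore,
    )


def build_top_hits(
    hits: Iterable[BlastHit],
    query_lengths: Mapping[str, int],
    params: DedupParams,
) -> list[TopHit]:
    """Group raw hits by query and select each query's top hit.

    Queries absent from ``query_lengths`` raise ``KeyError`` naming the query.
    """
    by_query: dict[str, list[BlastHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    tophits = []
    for query_id in sorted(by_query):
        if query_id not in query_lengths:
            raise KeyError(f"no length for query {query_id!r}")
        th = select_top_hit(by_query[query_id], params, query_lengths[query_id])
        if th is not None:
            tophits.append(th)
    return tophits


def interval_overlap_aa(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Number of integer positions shared by two inclusive intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def dedupe(tophits: Sequence[TopHit], params: DedupParams) -> list[UniqueTranscript]:
    """Collapse top hits into one :class:`UniqueTranscript` per subject.

    The representative is the longest-query member (ties: lexicographically
    smallest query id). Every other member is classified by its HSP overlap
    with the representative's subject interval: strictly more than
    ``overlap_threshold_aa`` shared residues makes it an isoform/paralogue,
    otherwise a fragment of the same transcript.
    """
    seen: set[str] = set()
    for th in tophits:
        if th.query_id in seen:
            raise ValueError(f"duplicate top hit for query {th.query_id!r}")
        seen.add(th.query_id)

    by_subject: dict[str, list[TopHit]] = {}
    for th in tophits:
        by_subject.setdefault(th.subject_id, []).append(th)

    groups = []
    for subject_id in sorted(by_subject):
        members = by_subject[subject_id]
        rep = min(members, key=lambda t: (-t.query_length, t.query_id))
        fragments, isoforms = [], []
        for th in sorted(members, key=lambda t: t.query_id):
            if th.query_id == rep.query_id:
                continue
            shared = interval_overlap_aa(th.subject_interval, rep.subject_interval)
            if shared > params.overlap_threshold_aa:
                isoforms.append(th.query_id)
            else:
                fragments.append(th.query_id)
        groups.append(
            UniqueTranscript(
                subject_id=subject_id,
                representative=rep.query_id,
                representative_length=rep.query_length,
                fragments=tuple(fragments),
                isoforms_or_paralogues=tuple(isoforms),
            )
        )
    return groups


def count_unique(groups: Sequence[UniqueTranscript]) -> int:
    """Number of unique transcripts = number of distinct top-hit subjects.

    Isoform/paralogue members are reported within their group but do not
    increment the count.
    """
    return len(groups)
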