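"""Gene-family expansion counts by isogroup collapse.

Putative paralogue counts per reference gene family: take every isotig whose
*top* BLAST hit falls inside the family's reference set, then collapse
isotigs sharing an isogroup to a single count (isotigs of one isogroup are
putative splice variants of one gene, not paralogues). Secondary hits never
qualify an isotig, and singletons are excluded by construction — they carry
no isogroup.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .dedup import TopHit

__all__ = ["ExpansionCount", "count_family_expansion"]


@dataclass(frozen=True)
class ExpansionCount:
    family_id: str
    counted_isogroups: int
    member_isotigs: tuple[str, ...]


def count_family_expansion(
    tophits: Mapping[str, TopHit],
    family_table: Mapping[str, frozenset[str] | set[str]],
    isotig_to_isogroup: Mapping[str, str],
) -> list[ExpansionCount]:
    """Distinct-isogroup counts per family, sorted by count descending.

    ``tophits`` maps isotig id → its selected top hit. An isotig whose top
    hit is in a family but which has no isogroup assignment raises
    ``ValueError`` naming the isotig.
    """
    counts = []
    for family_id in sorted(family_table):
        members = family_table[family_id]
        isotigs = sorted(
            q for q, th in tophits.items() if th.subject_id in members
        )
        isogroups = set()
        for isotig in isotigs:
            if isotig not in isotig_to_isogroup:
                raise ValueError(
                    f"isotig {isotig!r} hits family {family_id!r} "
                    "but has no isogroup assignment"
                )
            isogroups.add(isotig_to_isogroup[isotig])
        counts.append(
            ExpansionCount(
                family_id=family_id,
                counted_isogroups=len(isogroups),
                member_isotigs=tuple(isotigs),
            )
        )
    counts.sort(key=lambda c: (-c.counted_isogroups, c.family_id))
    return counts
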