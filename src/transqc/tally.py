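"""Species/clade tallies of top BLAST hits and category-proportion profiles."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .dedup import UniqueTranscript
from .stats import percent

__all__ = ["tally_species", "aggregate_clades", "category_proportions", "OTHER"]

#: Bucket for subjects or species absent from the supplied maps.
OTHER = "other"


def tally_species(
    groups: Iterable[UniqueTranscript],
    subject_to_species: Mapping[str, str],
) -> dict[str, tuple[int, float]]:
    """Tally the species of each group's top-hit subject.

    Returns species → (count, proportion); unmapped subjects fall into
    ``"other"``. Proportions sum to 1 over all species.
    """
    counts: dict[str, int] = {}
    total = 0
    for g in groups:
        species = subject_to_species.get(g.subject_id, OTHER)
        counts[species] = counts.get(species, 0) + 1
        total += 1
    if total == 0:
        return {}
    return {sp: (c, c / total) for sp, c in sorted(counts.items())}


def aggregate_clades(
    species_tally: Mapping[str, tuple[int, float]],
    species_to_clade: Mapping[str, str],
) -> dict[str, tuple[int, float]]:
    """Aggregate a species tally to clades; unmapped species go to "other".

    Counts are conserved: clade counts sum to the species-count total.
    """
    counts: dict[str, int] = {}
    total = 0
    for species, (count, _) in species_tally.items():
        clade = species_to_clade.get(species, OTHER)
        counts[clade] = counts.get(clade, 0) + count
        total += count
    if total == 0:
        return {}
    return {cl: (c, c / total) for cl, c in sorted(counts.items())}


def category_proportions(
    annotation_table: Mapping[str, set[str] | frozenset[str]],
    categories: Sequence[str],
) -> dict[str, float]:
    """Percentage of annotated ids carrying each listed category.

    The denominator is the number of ids with at least one category; ids
    with no categories are excluded from it. Percentages use the shared
    one-decimal formatter and need not sum to 100 (an id may carry several
    categories).
    """
    if not categories:
        raise ValueError("category list must be nonempty")
    annotated = [labels for labels in annotation_table.values() if labels]
    if not annotated:
        raise ValueError("no annotated ids")
    return {
        cat: percent(sum(1 for labels in annotated if cat in labels), len(annotated))
        for cat in categories
    }
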