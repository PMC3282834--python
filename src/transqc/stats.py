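"""Assembly summary statistics: counts, N50, coverage, and percentages.

The percentage formatter here is the single formatter used for every reported
percentage in the package (half-up rounding to one decimal), so that figures
printed by different stages are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .io import AssemblyProduct

__all__ = [
    "ReadAccounting",
    "SummaryReport",
    "n50",
    "contig_coverage",
    "percent",
    "summarize_assembly",
]


def n50(lengths: Sequence[int]) -> int:
    """N50 of a set of sequence lengths.

    The largest length L such that sequences of length >= L together contain
    at least half the total bases; computed by sorting descending and walking
    the cumulative sum. With an even split exactly at L, L is returned.
    """
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    total = sum(lengths)
    half = total / 2
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if acc >= half:
            return l
    raise AssertionError("unreachable")  # pragma: no cover


def contig_coverage(contig_length: int, read_bases: int) -> float:
    """Per-contig coverage: total read bases used to build the contig divided
    by the contig length (reads/bp)."""
    if contig_length <= 0:
        raise ValueError("contig_length must be positive")
    if read_bases < 0:
        raise ValueError("read_bases must be nonnegative")
    return read_bases / contig_length


def percent(numerator: int, denominator: int) -> float:
    """100*numerator/denominator rounded half-up to one decimal.

    Shared by every module that reports a percentage.
    """
    if denominator == 0:
        raise ZeroDivisionError("percent with zero denominator")
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ReadAccounting:
    """Read counts through screening and assembly.

    ``screened_reads`` is the number of reads subjected to assembly after
    adapter/quality screening; the four ``excluded_*`` fields are the reads
    the assembler dropped (partially assembled, repeat, outlier, too short).
    """

    raw_reads: int = 0
    screened_reads: int = 0
    assembled_reads: int = 0
    singletons: int = 0
    excluded_partial: int = 0
    excluded_repeat: int = 0
    excluded_outlier: int = 0
    excluded_short: int = 0

    @property
    def excluded_total(self) -> int:
        return (
            self.excluded_partial
            + self.excluded_repeat
            + self.excluded_outlier
            + self.excluded_short
        )

    def conserved(self) -> bool:
        """assembled + singletons + excluded == screened."""
        return (
            self.assembled_reads + self.singletons + self.excluded_total
            == self.screened_reads
        )


@dataclass
class SummaryReport:
    raw_reads: int = 0
    screened_reads: int = 0
    assembled_reads: int = 0
    singletons: int = 0
    excluded_partial: int = 0
    excluded_repeat: int = 0
    excluded_outlier: int = 0
    excluded_short: int = 0
    excluded_total: int = 0
    n_isotigs: int = 0
    n_contigs: int = 0
    n_isogroups: int = 0
    n_singleton_products: int = 0
    isotig_n50: int | None = None
    mean_contigs_per_isotig: float | None = None
    mean_isotigs_per_isogroup: float | None = None
    read_conservation_ok: bool | None = None
    percentages: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "percentages"}
        for name, value in self.percentages.items():
            d[f"pct_{name}"] = value
        return d


def summarize_assembly(
    products: Iterable[AssemblyProduct],
    accounting: ReadAccounting | None = None,
) -> SummaryReport:
    """Assemble the summary report from products plus optional read counts.

    Denominators are explicit in each percentage key (``_of_screened``,
    ``_of_raw``) so no guessing is needed about which count a figure is
    relative to. When contig products are present, every contig referenced by
    an isotig must exist; orphans raise ``ValueError`` listing the ids.
    """
    products = list(products)
    isotigs = [p for p in products if p.category == "isotig"]
    contigs = [p for p in products if p.category == "contig"]
    singles = [p for p in products if p.category == "singleton"]

    referenced = {cid for p in isotigs for cid in p.contig_ids}
    if contigs:
        present = {p.id for p in contigs}
        orphans = sorted(referenced - present)
        if orphans:
            raise ValueError(f"isotigs reference unknown contigs: {orphans}")

    isogroups = {p.isogroup_id for p in isotigs if p.isogroup_id}
    n_contigs = len(contigs) if contigs else len(referenced)

    report = SummaryReport(
        n_isotigs=len(isotigs),
        n_contigs=n_contigs,
        n_isogroups=len(isogroups),
        n_singleton_products=len(singles),
    )
    if isotigs:
        report.isotig_n50 = n50([len(p) for p in isotigs])
        with_contigs = [p for p in isotigs if p.contig_ids]
        if with_contigs:
            report.mean_contigs_per_isotig = sum(
                len(p.contig_ids) for p in with_contigs
            ) / len(with_contigs)
        if isogroups:
            assigned = sum(1 for p in isotigs if p.isogroup_id)
            report.mean_isotigs_per_isogroup = assigned / len(isogroups)

    if accounting is not None:
        report.raw_reads = accounting.raw_reads
        report.screened_reads = accounting.screened_reads
        report.assembled_reads = accounting.assembled_reads
        report.singletons = accounting.singletons
        report.excluded_partial = accounting.excluded_partial
        report.excluded_repeat = accounting.excluded_repeat
        report.excluded_outlier = accounting.excluded_outlier
        report.excluded_short = accounting.excluded_short
        report.excluded_total = accounting.excluded_total
        report.read_conservation_ok = accounting.conserved()
        pct = report.percentages
        if accounting.raw_reads:
            pct["screened_of_raw"] = percent(
                accounting.screened_reads, accounting.raw_reads
            )
        if accounting.screened_reads:
            pct["assembled_of_screened"] = percent(
                accounting.assembled_reads, accounting.screened_reads
            )
            pct["singletons_of_screened"] = percent(
                accounting.singletons, accounting.screened_reads
            )
            pct["excluded_of_screened"] = percent(
                accounting.excluded_total, accounting.screened_reads
            )
            pct["excluded_partial_of_screened"] = percent(
                accounting.excluded_partial, accounting.screened_reads
            )
            pct["excluded_repeat_of_screened"] = percent(
                accounting.excluded_repeat, accounting.screened_reads
            )
            pct["excluded_outlier_of_screened"] = percent(
                accounting.excluded_outlier, accounting.screened_reads
            )
            pct["excluded_short_of_screened"] = percent(
                accounting.excluded_short, accounting.screened_reads
            )
    return report
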