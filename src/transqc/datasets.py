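"""Published summary counts for the P. hawaiensis 454 transcriptome.

These are the printed dataset-level counts from the published
maternal/embryonic *Parhyale hawaiensis* transcriptome assembly (454
Titanium reads, Newbler v2.5, BLASTX against nr at an E-value cutoff of
1e-10). They are inputs for the report modules: the package recomputes every
derived figure (percentages, totals, per-category unique-hit sums) from
these raw counts rather than storing the derived numbers.
"""

from __future__ import annotations

from .stats import ReadAccounting

__all__ = [
    "PARHYALE_READS",
    "PARHYALE_COUNTS",
    "PARHYALE_BLAST",
    "PARHYALE_BLAST_1E5",
]

#: Read accounting through screening and assembly.
PARHYALE_READS = ReadAccounting(
    raw_reads=3_172_925,
    screened_reads=3_157_373,
    assembled_reads=2_349_266,
    singletons=276_564,
    excluded_partial=431_372,
    excluded_repeat=5_022,
    excluded_outlier=86_822,
    excluded_short=8_327,
)

#: Assembly product counts.
PARHYALE_COUNTS = {
    "raw_bases": 1_179_544_291,
    "isotigs": 35_301,
    "contigs": 89_664,
    "isogroups": 25_735,
    "singletons": 276_564,
    "isotig_n50": 1_510,
    "single_contig_isotigs": 18_615,
    "single_isotig_isogroups": 18_565,
}

#: BLASTX-vs-nr hit counts at the 1e-10 cutoff, per product category.
PARHYALE_BLAST = {
    "isotigs_total": 35_301,
    "isotigs_with_hit": 10_424,
    "isotigs_unique_hits": 10_203,
    "contigs_total": 89_664,
    "contigs_with_hit": 9_715,
    "singletons_total": 276_564,
    "singletons_with_hit": 9_583,
    "singletons_unique_hits": 8_864,
    "nonredundant_total": 311_865,  # isotigs + singletons
    "nonredundant_with_hit": 20_007,
    "isotigs_no_hit": 24_877,
    "singletons_no_hit": 266_981,
}

#: Unique-hit count under the relaxed 1e-5 cutoff profile.
PARHYALE_BLAST_1E5 = {"nonredundant_unique_hits": 26_494}
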