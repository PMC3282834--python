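#!/usr/bin/env python
"""Assembly summary statistics: published counts and the synthetic bundle.

Recomputes every derived figure of the published P. hawaiensis assembly
table from its raw counts (totals, one-decimal percentages), then builds
the same report for the synthetic bundle from step 01 and checks the
read-conservation invariant. Writes results/assembly_summary.json.
"""

import json
from pathlib import Path

from transqc import datasets
from transqc.io import load_products, read_contig_table, read_fasta, read_isogroup_table
from transqc.stats import percent, summarize_assembly

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "scratch" / "bundle"
OUT = ROOT / "results" / "assembly_summary.json"


def main() -> None:
    acc = datasets.PARHYALE_READS
    published = summarize_assembly([], acc).to_dict()
    published["isotig_n50"] = datasets.PARHYALE_COUNTS["isotig_n50"]
    b = datasets.PARHYALE_BLAST
    published["pct_isotigs_with_hit"] = percent(
        b["isotigs_with_hit"], b["isotigs_total"])
    print("published accounting: "
          f"{acc.screened_reads:,} screened reads, "
          f"{percent(acc.assembled_reads, acc.screened_reads)}% assembled, "
          f"{percent(acc.singletons, acc.screened_reads)}% singletons, "
          f"{percent(acc.excluded_total, acc.screened_reads)}% excluded "
          f"(conserved: {acc.conserved()})")

    products = load_products(
        BUNDLE / "products.fasta",
        read_isogroup_table(BUNDLE / "isotig_isogroup.tsv"),
        read_contig_table(BUNDLE / "isotig_contigs.tsv"),
    )
    synthetic = summarize_assembly(products).to_dict()
    print(f"synthetic bundle: {synthetic['n_isotigs']} isotigs in "
          f"{synthetic['n_isogroups']} isogroups "
          f"(+{synthetic['n_singleton_products']} singletons), "
          f"isotig N50 = {synthetic['isotig_n50']} bp, "
          f"mean contigs/isotig = {synthetic['mean_contigs_per_isotig']:.2f}, "
          f"mean isotigs/isogroup = {synthetic['mean_isotigs_per_isogroup']:.2f}")

    OUT.write_text(json.dumps(
        {"published": published, "synthetic": synthetic}, indent=1) + "\n")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
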