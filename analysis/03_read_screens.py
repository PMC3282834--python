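#!/usr/bin/env python
"""Pre-assembly read screens: splice leaders, then C2H2 zinc fingers.

Screens the synthetic reads for the splice-leader prefix (trim or discard)
and the assembly products for C2H2 motif-encoding frames (remove), then
compares both against the generator's planted truth. Writes
results/screen_report.json.
"""

import json
from pathlib import Path

from transqc.io import SeqRecord, read_fasta
from transqc.leader import LeaderParams, screen_splice_leader
from transqc.motifs import filter_c2h2

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "scratch" / "bundle"
OUT = ROOT / "results" / "screen_report.json"


def main() -> None:
    truth = json.loads((BUNDLE / "truth.json").read_text())
    reads = read_fasta(BUNDLE / "reads.fasta")
    sls = tuple(r.seq for r in read_fasta(BUNDLE / "sl.fasta"))

    result = screen_splice_leader(reads, LeaderParams(sl_sequences=sls))
    rep = result.report
    planted_sl = {
        rid for rid, pid in truth["reads"].items()
        if truth["genes"][truth["products"][pid]["gene_id"]]["sl"]
    }
    affected = {r.id for r in result.trimmed + result.discarded}
    print(f"splice-leader screen: {rep['trimmed']} trimmed, "
          f"{rep['discarded']} discarded of {rep['total']} reads "
          f"({100 * rep['affected_fraction']:.2f}%); "
          f"planted SL reads recovered exactly: {affected == planted_sl}")

    products = read_fasta(BUNDLE / "products.fasta")
    kept, removed, mrep = filter_c2h2(products, mode="nucleotide")
    motif_genes = {g for g, rec in truth["genes"].items() if rec["motif"]}
    removed_genes = {
        truth["products"][r.id]["gene_id"] for r in removed
    }
    print(f"C2H2 screen: removed {mrep['removed']} of {mrep['total']} products "
          f"({100 * mrep['removed_fraction']:.2f}%); removed products come from "
          f"{len(removed_genes)} genes, {len(removed_genes & motif_genes)} of "
          f"which carry a planted motif")

    OUT.write_text(json.dumps({
        "splice_leader": rep,
        "sl_planted_recovered_exactly": affected == planted_sl,
        "c2h2": mrep,
        "c2h2_removed_genes": len(removed_genes),
        "c2h2_removed_planted_genes": len(removed_genes & motif_genes),
    }, indent=1) + "\n")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
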