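#!/usr/bin/env python
"""Species/clade tallies of top hits, before and after the C2H2 screen.

The generator assigns motif-carrying genes to a phylogenetically
far-removed decoy species, emulating how zinc-finger-rich transcripts can
inflate one clade's apparent share of top BLAST hits. This step tallies
clades on the full deduplicated set, repeats the tally after removing
motif-carrying products, and reports the decoy clade's drop. Writes
results/clade_tally.tsv.
"""

from pathlib import Path

from transqc.dedup import DedupParams, build_top_hits, dedupe
from transqc.io import read_blast_tabular, read_fasta, read_species_map
from transqc.motifs import filter_c2h2
from transqc.tally import aggregate_clades, tally_species

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "scratch" / "bundle"
OUT = ROOT / "results" / "clade_tally.tsv"


def clade_tally(hits, lengths, subject_species, species_clade, params):
    groups = dedupe(build_top_hits(hits, lengths, params), params)
    return aggregate_clades(tally_species(groups, subject_species), species_clade)


def main() -> None:
    params = DedupParams()
    hits = read_blast_tabular(BUNDLE / "blast.tsv")
    products = read_fasta(BUNDLE / "products.fasta")
    lengths = {r.id: len(r.seq) for r in products}
    subject_species, species_clade = read_species_map(BUNDLE / "species_map.tsv")

    before = clade_tally(hits, lengths, subject_species, species_clade, params)
    kept, removed, _ = filter_c2h2(products, mode="nucleotide")
    kept_ids = {r.id for r in kept}
    after = clade_tally([h for h in hits if h.query_id in kept_ids],
                        lengths, subject_species, species_clade, params)

    with OUT.open("w") as fh:
        fh.write("clade\tcount_before\tprop_before\tcount_after\tprop_after\tdelta\n")
        for clade in sorted(set(before) | set(after)):
            cb, pb = before.get(clade, (0, 0.0))
            ca, pa = after.get(clade, (0, 0.0))
            fh.write(f"{clade}\t{cb}\t{pb:.4f}\t{ca}\t{pa:.4f}\t{pa - pb:+.4f}\n")
            print(f"{clade}: {100 * pb:.1f}% of unique hits before screen, "
                  f"{100 * pa:.1f}% after ({100 * (pa - pb):+.1f} points)")
    decoy = "Amphioxus"
    dropped = after.get(decoy, (0, 0.0))[1] < before.get(decoy, (0, 1.0))[1]
    print(f"decoy clade share dropped after motif screening: {dropped}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
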