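# Methods

This note documents the models and procedures implemented in `transqc`,
the parameters that matter, the synthetic data the test suite runs on, and
the numerical choices made where the design was genuinely open.

## Unique-transcript estimation (`transqc.dedup`)

A *de novo* assembly fragments transcripts, so the number of assembly
products with BLAST hits overestimates gene content. The estimator groups
products by the subject of their top BLAST hit and asks whether two
same-subject products cover the same region of that protein.

**Top-hit selection.** A hit passes if its E-value is ≤ the cutoff
(default 10⁻¹⁰; a relaxed 10⁻⁵ profile is available via `--evalue`). The
top hit is the passing row with minimum E-value; ties break by maximum
bitscore, then input order. When the winning query–subject pair has
several HSPs, the subject interval reported is the highest-bitscore HSP's.
These tie-break rules are declared conventions of this implementation —
common BLAST practice, but not forced by any external definition — and are
therefore stated here rather than inferred.

**Classification.** Within a subject group, the representative is the
longest-query member (ties: lexicographically smallest id). Every other
member is compared *pairwise to the representative* by inclusive-interval
overlap in subject (amino-acid) coordinates:
`overlap > overlap_threshold_aa` (default 14) ⇒ isoform/paralogue,
otherwise fragment. Overlap is measured on the subject because fragments
of one transcript align to different regions of the same protein; the 14
aa threshold sits just above the assembler's minimum read overlap
(40 nt ≈ 13.3 aa), so any smaller sharing could not have been assembled
anyway. Representative-anchored (rather than transitive-closure)
classification is deterministic and order-independent; with mixed chains
(A overlaps B, B overlaps C, A disjoint from C) a transitive rule would be
order-sensitive.

**Counting.** The unique-transcript count is the number of distinct
top-hit subjects; isoform/paralogue members are reported but never
increment the count. Isotigs and singletons may be deduplicated per
category (the default, matching how such totals are reported — category
counts are added) or jointly (`--joint`). Per-category totals count a gene
once per category when its products span both; the joint count is the one
comparable to the generator's gene truth. Cross-subject clustering is
deliberately out of scope: two fragments of one transcript with different
top subjects stay two unique transcripts, an acknowledged overestimation
source of the method itself.

## C2H2 zinc-finger screen (`transqc.motifs`)

The low-stringency degenerate motif
`X2-C-X{1,2,4,5}-C-X12-H-X{3-6}-(H,C)` is matched positionally:

- wildcard (X) positions accept any residue including the unknown-residue
  code X, but never a stop (`*`); matches cannot span stops;
- the four coordinating anchors require literal C/H; the parenthesized
  trailing alternative admits the C2HC variant finger;
- the gap between the second cysteine and the first histidine is exactly
  12; the final gap is 3–6;
- every match start is reported (overlapping matches allowed); per start,
  the shortest satisfying span is returned (span ambiguity is harmless
  because filtering only uses presence/absence).

Medium/high stringency patterns are config-supplied `PatternSpec` objects,
not hardcoded: only the low-stringency definition is available in a
machine-readable form, and it is the one used for screening (it deliberately
over-captures "C2H2-like" domains).

Nucleotide inputs are translated in all six frames (standard code, stops
as `*`, any N-containing codon as X — a deliberate convention; ambiguity
resolution such as GCN→A is *not* performed so that N never silently
creates anchors) and a record is removed if any frame contains a match.
Whether the original screen translated reads or encoded the motif at the
nucleotide level is unrecorded; six-frame translation is the declared
choice here. Note that six-frame screening has an intrinsic false-positive
channel: a motif can appear by chance in a non-coding frame of a clean
coding sequence (observed at roughly 1% of motif-free synthetic products),
which is accepted since the screen's purpose is aggressive removal.

Tandem fingers: the count is the number of ordered match pairs where the
literal linker `TGEKP` immediately follows the first match's end and the
second match starts immediately after the linker.

## Splice-leader screen (`transqc.leader`)

Trans-spliced transcripts carry a species-specific leader (SL) at the 5′
end. Leaders are an *input file*, never hardcoded. Detection is windowed
Hamming matching — deterministic and testable, in contrast to the
unpublished vector-trimming heuristics this emulates:

- each SL and its reverse complement (454 reads are unstranded) is slid
  over the first `search_window` bp (default 100);
- the best occurrence has fewest mismatches (≤ `max_mismatch`, default 2),
  ties leftmost;
- the read is trimmed from its 5′ end through the SL's 3′ end, repeatedly
  until no occurrence remains in the window (concatenated leaders occur);
- reads trimmed below `min_remaining` (default 40 bp, the assembler's
  minimum usable read length) are discarded.

Kept/trimmed/discarded partition the input exactly, and no surviving read
contains an SL occurrence within tolerance — both asserted by tests.

## Ortholog hit ratio (`transqc.ohr`)

For one query: take its top-hit subject, merge the subject-coordinate
intervals of all passing HSPs against that subject (inclusive intervals;
abutting intervals merge), and divide covered residues by subject length.
The subject-coverage convention (rather than counting non-gap query
residues) is the declared choice; with simulated exact hits the two
coincide. Threshold fractions use strict inequality (`ratio > t`,
matching "over 50%"), and the histogram uses 10 equal right-closed bins on
(0, 1].

## Family expansion (`transqc.families`)

Input: a family table (family id → reference subject ids), a top-hit map
for isotigs, and the isotig → isogroup table. An isotig qualifies only if
its *top* hit is in the family's reference set (a secondary hit inside the
family never qualifies); qualifying isotigs are collapsed to distinct
isogroups. Singletons are excluded by construction — they carry no
isogroup. The module is agnostic to which BLAST program produced the hit
table; it consumes any 12-column tabular file.

## Saturation (`transqc.saturation`)

One seeded permutation of the read ids is drawn; the subset at fraction f
is its first `round(f·N)` elements, so subsets are nested and the
discovery curve is non-decreasing whenever the caller-supplied `evaluate`
is monotone. Nested (rather than independent per-fraction) sampling is the
declared choice: it yields a monotone curve matching how such figures are
presented, and is cheaper. Assembly of subsets is delegated to `evaluate`;
the package never embeds an assembler (on synthetic data, `evaluate`
counts distinct true source genes).

The sampled curve is validated against the exact hypergeometric-inclusion
expectation: with per-gene read counts d_g and a subsample of m of N
reads, E[uniques] = G − Σ_g C(N−d_g, m)/C(N, m); the test also computes
the exact variance (pairwise covariances via C(N−d_g−d_h, m)/C(N, m)) and
requires the 20-seed mean within 3 standard deviations of the mean.

## Summary statistics (`transqc.stats`)

- **N50**: largest member length L with at least half the total bases in
  sequences of length ≥ L (descending cumulative sum; with an even split
  exactly at L, L is returned — the standard "at least half" rule).
- **percent**: `100·a/b` rounded **half-up** to one decimal. This single
  formatter produces every reported percentage; half-up matches every
  printed pair checked in the reference dataset (e.g. 3,157,373/3,172,925
  → 99.5).
- **Coverage**: read bases ÷ contig length, exact quotient. Genome-wide
  average coverage is total assembled read bases ÷ total assembly bases.
- **Read conservation**: assembled + singletons + Σ excluded = screened,
  checked and reported, with the denominator of every percentage explicit
  in its key (`_of_screened`, `_of_raw`) since reported figures mix
  denominators.

## The synthetic generator (`transqc.simulate`)

The generator is first-class, tested code; it emulates the study
conditions end to end with exact bookkeeping:

- **Proteins first.** Proteins (uniform residues, lengths U[150, 500] aa)
  are generated motif-free by rejection against the scanner; transcripts
  are reverse-translated with uniform synonymous codons. This keeps
  subject coordinates in amino-acid space exact and motif planting
  trivial.
- **Flags are exact counts**: `round(fraction · n_genes)` genes receive
  the motif / splice-leader flag. Motif genes get a planted finger (every
  second one a TGEKP-linked tandem pair); family members are ~5%
  point-mutated copies of a founder, re-rejected to stay motif-free.
- **Isoforms**: 72.1% of genes are single-isoform (cap 10, mirroring the
  reference assembly's isogroup-size cap); multi-isoform genes draw
  uniformly from {2, 3}, giving a mean of ≈1.4 isotigs per isogroup as in
  the reference dataset.
- **Fragments**: each isoform splits into 1–3 abutting sub-spans of ≥ 60
  aa, so deduplication classifies them as fragments (overlap 0) and every
  simulated hit passes the 10⁻¹⁰ cutoff.
- **Reads**: ~N(400, 150) bp clipped to [40, 1200], substrings of their
  product; SL-flagged genes' reads carry the leader prefix. A configurable
  fraction of products are emitted as 454-style singletons.
- **BLAST table**: one top hit per product with subject interval equal to
  the true span; E-values 10^(−0.25·aa + ε), ε ~ U(0, 2), floored at
  10⁻¹⁸⁰ to avoid float underflow — only order relations matter. Decoy
  secondary hits (other subjects, E-values 10³–10⁸ × worse, half the
  bitscore) are added at a configurable rate, and an exact
  `round(no_hit_fraction · n)` products are left out of the table
  (the reference dataset's ~70% no-hit class is available as a scenario).
- **Species map**: motif genes map to a far-removed decoy species/clade,
  the rest rotate through arthropods — reproducing the mechanism by which
  zinc-finger decoy hits inflate one clade before screening.
- Everything is a deterministic function of (spec, seed); each stage uses
  an independent seeded stream.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: 454 homopolymer errors and chimeras, quality
strings, realistic BLAST statistics (E-values are a toy monotone model),
assembly errors (fragments never cross gene boundaries; products map to
exactly one protein), non-coding sequence, and real phylogenetic breadth
of hit species. Tests on this generator demonstrate the *algorithms*
recover planted structure exactly; they say nothing about BLAST's own
sensitivity on diverged sequences.

## Problem sizes and determinism

The shipped analyses use a 1,000-gene scenario (~2,700 products, ~8,000
reads), which runs the full pipeline in a few seconds; unit and property
suites use 40–500-gene scenarios and 500–10,000 random oracle instances.
These sizes were chosen so results are exact and stable while the entire
suite stays interactive. All randomness flows from explicit seeds; reruns
are byte-identical.

## Known limitations

- Fragments of one transcript whose top hits are *different* subjects are
  counted as distinct transcripts (inherent to the method; documented
  overestimation source).
- The dataset-level headline numbers of the reference study (e.g. its
  absolute unique-hit count) depend on the original raw reads, the
  proprietary assembler, and a 2010 protein database snapshot; the package
  recomputes the study's *arithmetic* from its printed counts and
  validates the *methods* on synthetic truth, but does not re-derive those
  absolute numbers.
- Windowed Hamming SL matching does not model indels; a leader containing
  an insertion would be missed (real leaders are short enough that this is
  rare, and the tolerance is configurable).
- `ratio_histogram` places a ratio of exactly 0 in the first bin; the
  pipeline never produces zero-coverage records.
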