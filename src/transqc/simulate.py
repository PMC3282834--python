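"""Ground-truth transcriptome simulator.

Generates a synthetic gene set with known answers for every pipeline stage:
proteins (some carrying planted C2H2 zinc-finger motifs, some in paralogous
families), splice isoforms, fragmentation into Newbler-style assembly
products (isotigs with isogroup/contig membership, plus 454-style
singletons), reads with splice-leader prefixes on trans-spliced genes, and a
simulated top-hit BLAST table whose subject coordinates equal the true
fragment-to-protein mapping.

Design: proteins are generated first and transcripts reverse-translated with
uniform synonymous codons, which keeps subject coordinates in amino-acid
space exact and makes motif planting trivial. The E-value model is a simple
declared function of alignment length (10^(-0.25*aa + eps), eps ~ U(0,2)),
monotone enough that spans of 60 aa or more always pass a 1e-10 cutoff; only
order relations matter downstream. Everything is a deterministic function of
(spec, seed).

Default scenario parameters echo the shape of a real 454 maternal/embryonic
transcriptome (72.1% single-isoform genes capped at 10 isoforms, read
lengths ~N(400, 150) clipped to [40, 1200], a large no-hit class available
via ``no_hit_fraction``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import AssemblyProduct, BlastHit, SeqRecord, write_fasta, write_blast_tabular
from .motifs import LOW_STRINGENCY, MotifSpec, PatternSpec, scan_c2h2, TGEKP
from .stats import ReadAccounting

__all__ = [
    "TruthSpec",
    "GeneTruth",
    "ProductTruth",
    "TruthMap",
    "Bundle",
    "generate_truth",
    "fragment_transcripts",
    "simulate_blast",
    "simulate_bundle",
    "write_bundle",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Wildcard residues used when planting motifs (no C/H, so planted anchors
#: are exactly where intended).
_PLANT_AA = "".join(c for c in AA20 if c not in "CH")

#: Synthetic splice-leader used by default (an arbitrary fixed 26-mer, not a
#: real organism's leader; real leaders are supplied by the caller).
DEFAULT_SL = "ACTTGTAGCCTAAGTTCAGGTACCTG"

_ARTHROPODS = (
    ("Daphnia pulex", "Arthropoda"),
    ("Acyrthosiphon pisum", "Arthropoda"),
    ("Tribolium castaneum", "Arthropoda"),
    ("Drosophila melanogaster", "Arthropoda"),
)
#: Species/clade assigned to motif-flagged genes, emulating the way
#: zinc-finger-rich decoy hits concentrate in one far-removed clade.
_DECOY_SPECIES = ("Branchiostoma floridae", "Amphioxus")

# codon table for uniform synonymous reverse translation
_AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
from Bio.Data.CodonTable import standard_dna_table as _tbl  # noqa: E402

for _codon, _aa in _tbl.forward_table.items():
    _AA_TO_CODONS.setdefault(_aa, tuple())
    _AA_TO_CODONS[_aa] = _AA_TO_CODONS[_aa] + (_codon,)


@dataclass(frozen=True)
class TruthSpec:
    """Parameters of the synthetic transcriptome.

    Fractions are exact: ``round(fraction * n_genes)`` genes receive each
    flag. ``families`` lists (family_id, size) pairs whose members are
    near-duplicate (point-mutated) proteins. ``fragments_per_transcript`` is
    an inclusive uniform range; fragments tile the isoform span without
    overlap so downstream deduplication classifies them as fragments of one
    transcript.
    """

    n_genes: int = 100
    seed: int = 0
    p_single_isoform: float = 0.721
    isoform_cap: int = 10
    multi_isoform_choices: tuple[int, ...] = (2, 3)
    families: tuple[tuple[str, int], ...] = ()
    motif_fraction: float = 0.0
    sl_fraction: float = 0.0
    fragments_per_transcript: tuple[int, int] = (1, 3)
    min_fragment_aa: int = 60
    protein_length_range: tuple[int, int] = (150, 500)
    read_length_mean: float = 400.0
    read_length_sd: float = 150.0
    read_length_min: int = 40
    read_length_max: int = 1200
    depth_per_transcript: int = 5
    singleton_fraction: float = 0.1
    no_hit_fraction: float = 0.0
    decoy_rate: float = 0.0
    sl_sequence: str = DEFAULT_SL

    def __post_init__(self) -> None:
        for name in ("motif_fraction", "sl_fraction", "singleton_fraction",
                     "no_hit_fraction", "decoy_rate", "p_single_isoform"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_genes < 0:
            raise ValueError("n_genes must be nonnegative")
        if sum(size for _, size in self.families) > self.n_genes:
            raise ValueError("family sizes exceed n_genes")
        if any(k < 2 or k > self.isoform_cap for k in self.multi_isoform_choices):
            raise ValueError("multi-isoform choices must lie in [2, isoform_cap]")
        if self.fragments_per_transcript[0] < 1:
            raise ValueError("fragments_per_transcript lower bound must be >= 1")


@dataclass
class GeneTruth:
    gene_id: str
    protein_id: str
    protein: str
    family_id: str | None = None
    motif: bool = False
    tandem: bool = False
    sl: bool = False


@dataclass
class ProductTruth:
    product_id: str
    gene_id: str
    span: tuple[int, int]  # 1-based inclusive, protein (aa) coordinates
    category: str
    isogroup_id: str | None
    isoform_index: int


@dataclass
class TruthMap:
    """Ground truth: gene → isoforms → fragments → reads."""

    spec: TruthSpec
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    products: dict[str, ProductTruth] = field(default_factory=dict)
    reads: dict[str, str] = field(default_factory=dict)  # read_id → product_id

    def hit_bearing_genes(self, product_ids: set[str]) -> set[str]:
        """Genes with at least one product in ``product_ids``."""
        return {
            pt.gene_id for pid, pt in self.products.items() if pid in product_ids
        }


def _rng(spec: TruthSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed % (2**31), stream])


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _motif_free_protein(rng: np.random.Generator, length: int) -> str:
    while True:
        p = _random_protein(rng, length)
        if not scan_c2h2(p):
            return p


def _mutate(rng: np.random.Generator, protein: str, rate: float = 0.05) -> str:
    """Point-mutate ~rate of positions, keeping the result motif-free."""
    n = max(1, int(rate * len(protein)))
    for _ in range(100):
        chars = list(protein)
        for pos in rng.choice(len(chars), size=n, replace=False):
            choices = [a for a in AA20 if a != chars[pos]]
            chars[pos] = choices[int(rng.integers(len(choices)))]
        mutated = "".join(chars)
        if not scan_c2h2(mutated):
            return mutated
    raise RuntimeError("could not produce a motif-free mutant")  # pragma: no cover


def _build_finger(rng: np.random.Generator, pat: PatternSpec = LOW_STRINGENCY) -> str:
    """One concrete motif instance with random gaps and wildcards."""
    g1 = int(rng.choice(pat.gap1))
    g2 = int(rng.choice(pat.gap2))
    g3 = int(rng.choice(pat.gap3))
    w = lambda k: "".join(rng.choice(list(_PLANT_AA), size=k))
    final = pat.final[int(rng.integers(len(pat.final)))]
    return w(pat.leading_x) + "C" + w(g1) + "C" + w(g2) + "H" + w(g3) + final


def _plant(rng: np.random.Generator, protein: str, tandem: bool) -> str:
    """Replace a random slice of the protein with a planted motif
    (or a TGEKP-linked tandem pair)."""
    insert = _build_finger(rng)
    if tandem:
        insert = insert + TGEKP + _build_finger(rng)
    if len(protein) < len(insert):
        raise ValueError("protein too short for motif planting")
    pos = int(rng.integers(0, len(protein) - len(insert) + 1))
    planted = protein[:pos] + insert + protein[pos + len(insert) :]
    assert scan_c2h2(planted), "planted motif must be detectable"
    return planted


def generate_truth(spec: TruthSpec) -> TruthMap:
    """Generate the gene-level ground truth (proteins, families, flags).

    Non-flagged proteins are motif-free by rejection against the scanner;
    motif-flagged proteins carry at least one planted low-stringency C2H2
    motif, and every second flagged gene carries a TGEKP-linked tandem pair.
    """
    truth = TruthMap(spec=spec)
    n = spec.n_genes
    if n == 0:
        return truth
    rng = _rng(spec, 11)

    width = max(5, len(str(n)))
    gene_ids = [f"gene{i + 1:0{width}d}" for i in range(n)]
    prot_ids = [f"prot{i + 1:0{width}d}" for i in range(n)]

    # family membership consumes the first genes in order
    family_of: dict[int, str] = {}
    cursor = 0
    for family_id, size in spec.families:
        for _ in range(size):
            family_of[cursor] = family_id
            cursor += 1

    n_motif = round(spec.motif_fraction * n)
    motif_idx = sorted(rng.choice(n, size=n_motif, replace=False).tolist())
    n_sl = round(spec.sl_fraction * n)
    sl_idx = set(rng.choice(n, size=n_sl, replace=False).tolist())

    lo, hi = spec.protein_length_range
    founders: dict[str, str] = {}
    for i in range(n):
        family_id = family_of.get(i)
        if family_id is not None and family_id in founders:
            protein = _mutate(rng, founders[family_id])
        else:
            protein = _motif_free_protein(rng, int(rng.integers(lo, hi + 1)))
            if family_id is not None:
                founders[family_id] = protein
        truth.genes[gene_ids[i]] = GeneTruth(
            gene_id=gene_ids[i],
            protein_id=prot_ids[i],
            protein=protein,
            family_id=family_id,
            sl=i in sl_idx,
        )

    for rank, i in enumerate(motif_idx):
        g = truth.genes[gene_ids[i]]
        g.motif = True
        g.tandem = rank % 2 == 1  # half of flagged genes get a tandem pair
        g.protein = _plant(rng, g.protein, g.tandem)
    return truth


def _reverse_translate(rng: np.random.Generator, peptide: str) -> str:
    return "".join(
        _AA_TO_CODONS[aa][int(rng.integers(len(_AA_TO_CODONS[aa])))]
        for aa in peptide
    )


def _tile_span(
    span: tuple[int, int], n_frag: int, min_aa: int
) -> list[tuple[int, int]]:
    """Split a span into up to n_frag abutting (non-overlapping) chunks of at
    least ``min_aa`` residues each."""
    start, end = span
    length = end - start + 1
    n_frag = max(1, min(n_frag, length // min_aa)) if length >= min_aa else 1
    base = length // n_frag
    spans = []
    pos = start
    for j in range(n_frag):
        chunk = base if j < n_frag - 1 else end - pos + 1
        spans.append((pos, pos + chunk - 1))
        pos += chunk
    return spans


def fragment_transcripts(
    truth: TruthMap, spec: TruthSpec | None = None
) -> tuple[list[AssemblyProduct], list[SeqRecord]]:
    """Fragment each gene's isoforms into assembly products and reads.

    Populates ``truth.products`` and ``truth.reads`` in place and returns
    (products, reads). Products from the same gene share an isogroup;
    fragments of one isoform tile its span without overlap; a configurable
    fraction of products are emitted as 454-style singletons (no isogroup).
    Reads of SL-flagged genes carry the splice-leader prefix.
    """
    spec = spec or truth.spec
    rng = _rng(spec, 12)
    products: list[AssemblyProduct] = []
    reads: list[SeqRecord] = []
    isotig_n = contig_n = isogroup_n = read_n = 0
    singleton_ids: set[str] = set()
    alphabet = list("ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789")

    for gene_id in sorted(truth.genes):
        gene = truth.genes[gene_id]
        L = len(gene.protein)
        if rng.random() < spec.p_single_isoform:
            k = 1
        else:
            k = int(rng.choice(spec.multi_isoform_choices))
        gene_isogroup: str | None = None
        for iso in range(k):
            if iso == 0 or L <= spec.min_fragment_aa:
                iso_span = (1, L)
            else:
                li = int(rng.integers(max(spec.min_fragment_aa, 2 * L // 3), L + 1))
                s = int(rng.integers(1, L - li + 2))
                iso_span = (s, s + li - 1)
            lo_f, hi_f = spec.fragments_per_transcript
            n_frag = int(rng.integers(lo_f, hi_f + 1))
            for frag_span in _tile_span(iso_span, n_frag, spec.min_fragment_aa):
                peptide = gene.protein[frag_span[0] - 1 : frag_span[1]]
                nt = _reverse_translate(rng, peptide)
                if rng.random() < spec.singleton_fraction:
                    while True:
                        pid = "G" + "".join(rng.choice(alphabet, size=13))
                        if pid not in singleton_ids:
                            break
                    singleton_ids.add(pid)
                    product = AssemblyProduct(id=pid, category="singleton", seq=nt)
                else:
                    isotig_n += 1
                    pid = f"isotig{isotig_n:05d}"
                    if gene_isogroup is None:
                        isogroup_n += 1
                        gene_isogroup = f"isogroup{isogroup_n:05d}"
                    n_c = int(rng.integers(1, 4))
                    contig_ids = tuple(
                        f"contig{contig_n + j + 1:05d}" for j in range(n_c)
                    )
                    contig_n += n_c
                    product = AssemblyProduct(
                        id=pid,
                        category="isotig",
                        seq=nt,
                        isogroup_id=gene_isogroup,
                        contig_ids=contig_ids,
                    )
                products.append(product)
                truth.products[pid] = ProductTruth(
                    product_id=pid,
                    gene_id=gene_id,
                    span=frag_span,
                    category=product.category,
                    isogroup_id=product.isogroup_id,
                    isoform_index=iso,
                )
                for _ in range(spec.depth_per_transcript):
                    read_n += 1
                    rl = int(
                        np.clip(
                            rng.normal(spec.read_length_mean, spec.read_length_sd),
                            spec.read_length_min,
                            spec.read_length_max,
                        )
                    )
                    if rl >= len(nt):
                        rseq = nt
                    else:
                        rs = int(rng.integers(0, len(nt) - rl + 1))
                        rseq = nt[rs : rs + rl]
                    if gene.sl:
                        rseq = spec.sl_sequence + rseq
                    rid = f"r{read_n:07d}"
                    reads.append(SeqRecord(id=rid, seq=rseq))
                    truth.reads[rid] = pid
    return products, reads


_EXP_FLOOR = -180.0  # keeps simulated E-values away from float underflow


def simulate_blast(
    products: Sequence[AssemblyProduct],
    truth: TruthMap,
    spec: TruthSpec | None = None,
) -> tuple[list[BlastHit], dict[str, int]]:
    """Simulate a top-hit BLAST table consistent with the ground truth.

    Every hit-bearing product gets one hit against its true source protein
    with subject coordinates equal to the true sub-span; decoy secondary
    hits (other subjects, strictly worse E-values and bitscores) are added
    at ``decoy_rate``; exactly ``round(no_hit_fraction * n)`` products are
    left out of the table entirely.
    """
    spec = spec or truth.spec
    rng = _rng(spec, 13)
    subject_lengths = {
        g.protein_id: len(g.protein) for g in truth.genes.values()
    }
    prot_ids = sorted(subject_lengths)
    n = len(products)
    n_nohit = round(spec.no_hit_fraction * n)
    nohit = set(rng.choice(n, size=n_nohit, replace=False).tolist())
    hits: list[BlastHit] = []
    for i, product in enumerate(products):
        if i in nohit:
            continue
        pt = truth.products[product.id]
        gene = truth.genes[pt.gene_id]
        aln = pt.span[1] - pt.span[0] + 1
        exponent = max(-0.25 * aln + rng.uniform(0, 2), _EXP_FLOOR)
        evalue = 10.0 ** exponent
        pct = round(float(rng.uniform(95, 100)), 2)
        bitscore = round(2.0 * aln - float(rng.uniform(0, 5)), 1)
        hits.append(
            BlastHit(
                query_id=product.id,
                subject_id=gene.protein_id,
                pct_identity=pct,
                aln_length=aln,
                mismatches=int(aln * (100 - pct) / 100),
                gap_opens=0,
                q_start=1,
                q_end=3 * aln,
                s_start=pt.span[0],
                s_end=pt.span[1],
                evalue=evalue,
                bitscore=bitscore,
            )
        )
        if len(prot_ids) > 1 and rng.random() < spec.decoy_rate:
            others = [p for p in prot_ids if p != gene.protein_id]
            other = others[int(rng.integers(len(others)))]
            olen = subject_lengths[other]
            daln = min(aln, olen)
            ds = int(rng.integers(1, olen - daln + 2))
            dexp = min(exponent + float(rng.uniform(3, 8)), 2.0)
            hits.append(
                BlastHit(
                    query_id=product.id,
                    subject_id=other,
                    pct_identity=round(pct - 10.0, 2),
                    aln_length=daln,
                    mismatches=int(daln * 0.2),
                    gap_opens=0,
                    q_start=1,
                    q_end=3 * daln,
                    s_start=ds,
                    s_end=ds + daln - 1,
                    evalue=10.0 ** dexp,
                    bitscore=round(bitscore / 2, 1),
                )
            )
    return hits, subject_lengths


@dataclass
class Bundle:
    """Everything one synthetic scenario produces."""

    spec: TruthSpec
    truth: TruthMap
    products: list[AssemblyProduct]
    reads: list[SeqRecord]
    proteome: list[SeqRecord]
    hits: list[BlastHit]
    subject_lengths: dict[str, int]
    family_table: dict[str, frozenset[str]]
    subject_species: dict[str, str]
    species_clade: dict[str, str]
    accounting: ReadAccounting

    @property
    def isotig_to_isogroup(self) -> dict[str, str]:
        return {
            p.id: p.isogroup_id
            for p in self.products
            if p.category == "isotig" and p.isogroup_id
        }

    @property
    def isotig_to_contigs(self) -> dict[str, tuple[str, ...]]:
        return {
            p.id: p.contig_ids for p in self.products if p.category == "isotig"
        }


def simulate_bundle(spec: TruthSpec) -> Bundle:
    """Run the full generator: truth, products, reads, and BLAST table."""
    truth = generate_truth(spec)
    products, reads = fragment_transcripts(truth, spec)
    hits, subject_lengths = simulate_blast(products, truth, spec)

    proteome = [
        SeqRecord(id=g.protein_id, seq=g.protein)
        for g in (truth.genes[gid] for gid in sorted(truth.genes))
    ]
    family_table: dict[str, frozenset[str]] = {}
    for family_id, _ in spec.families:
        family_table[family_id] = frozenset(
            g.protein_id for g in truth.genes.values() if g.family_id == family_id
        )
    subject_species: dict[str, str] = {}
    species_clade: dict[str, str] = dict(_ARTHROPODS)
    species_clade[_DECOY_SPECIES[0]] = _DECOY_SPECIES[1]
    for i, gid in enumerate(sorted(truth.genes)):
        g = truth.genes[gid]
        if g.motif:
            subject_species[g.protein_id] = _DECOY_SPECIES[0]
        else:
            subject_species[g.protein_id] = _ARTHROPODS[i % len(_ARTHROPODS)][0]

    reads_per_product: dict[str, int] = {}
    for rid, pid in truth.reads.items():
        reads_per_product[pid] = reads_per_product.get(pid, 0) + 1
    assembled = sum(
        c
        for pid, c in reads_per_product.items()
        if truth.products[pid].category == "isotig"
    )
    singleton_reads = sum(
        c
        for pid, c in reads_per_product.items()
        if truth.products[pid].category == "singleton"
    )
    accounting = ReadAccounting(
        raw_reads=len(reads),
        screened_reads=len(reads),
        assembled_reads=assembled,
        singletons=singleton_reads,
    )
    return Bundle(
        spec=spec,
        truth=truth,
        products=products,
        reads=reads,
        proteome=proteome,
        hits=hits,
        subject_lengths=subject_lengths,
        family_table=family_table,
        subject_species=subject_species,
        species_clade=species_clade,
        accounting=accounting,
    )


def write_bundle(bundle: Bundle, outdir: str | Path) -> dict[str, str]:
    """Write the bundle as plain-text files; returns a name→path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "products": outdir / "products.fasta",
        "reads": outdir / "reads.fasta",
        "proteome": outdir / "proteome.fasta",
        "blast": outdir / "blast.tsv",
        "subject_lengths": outdir / "subject_lengths.tsv",
        "isotig_isogroup": outdir / "isotig_isogroup.tsv",
        "isotig_contigs": outdir / "isotig_contigs.tsv",
        "families": outdir / "families.tsv",
        "species_map": outdir / "species_map.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(
        (SeqRecord(id=p.id, seq=p.seq) for p in bundle.products), paths["products"]
    )
    write_fasta(bundle.reads, paths["reads"])
    write_fasta(bundle.proteome, paths["proteome"])
    write_blast_tabular(bundle.hits, paths["blast"])
    with paths["subject_lengths"].open("w") as fh:
        fh.write("subject_id\tlength_aa\n")
        for sid in sorted(bundle.subject_lengths):
            fh.write(f"{sid}\t{bundle.subject_lengths[sid]}\n")
    with paths["isotig_isogroup"].open("w") as fh:
        fh.write("isotig_id\tisogroup_id\n")
        for isotig, group in sorted(bundle.isotig_to_isogroup.items()):
            fh.write(f"{isotig}\t{group}\n")
    with paths["isotig_contigs"].open("w") as fh:
        fh.write("isotig_id\tcontig_ids\n")
        for isotig, contigs in sorted(bundle.isotig_to_contigs.items()):
            fh.write(f"{isotig}\t{','.join(contigs)}\n")
    with paths["families"].open("w") as fh:
        fh.write("family_id\tsubject_ids\n")
        for fam in sorted(bundle.family_table):
            fh.write(f"{fam}\t{','.join(sorted(bundle.family_table[fam]))}\n")
    with paths["species_map"].open("w") as fh:
        fh.write("subject_id\tspecies\tclade\n")
        for sid in sorted(bundle.subject_species):
            sp = bundle.subject_species[sid]
            fh.write(f"{sid}\t{sp}\t{bundle.species_clade.get(sp, 'other')}\n")
    truth_doc = {
        "spec": asdict(bundle.spec),
        "genes": {
            gid: {
                "protein_id": g.protein_id,
                "family_id": g.family_id,
                "motif": g.motif,
                "tandem": g.tandem,
                "sl": g.sl,
            }
            for gid, g in bundle.truth.genes.items()
        },
        "products": {
            pid: {
                "gene_id": pt.gene_id,
                "span": list(pt.span),
                "category": pt.category,
                "isogroup_id": pt.isogroup_id,
                "isoform_index": pt.isoform_index,
            }
            for pid, pt in bundle.truth.products.items()
        },
        "reads": bundle.truth.reads,
    }
    with paths["truth"].open("w") as fh:
        json.dump(truth_doc, fh, indent=1)
    return {name: str(p) for name, p in paths.items()}
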