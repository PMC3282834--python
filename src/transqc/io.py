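"""Readers and writers for the formats the pipeline touches.

Sequences travel as lightweight :class:`SeqRecord` objects (FASTA/FASTQ via
Biopython underneath), BLAST results as :class:`BlastHit` rows parsed from
12-column tabular output (``-outfmt 6`` dialect), and the various membership /
length / family / species tables as TSV files with a one-line header.

Coordinate convention: all parsed BLAST coordinates are 1-based inclusive.
Minus-strand hits (start > end in the raw file) are normalized so that
``start <= end`` and the original orientation is kept on the hit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "SeqRecord",
    "AssemblyProduct",
    "BlastHit",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "read_blast_tabular",
    "write_blast_tabular",
    "classify_product_id",
    "load_products",
    "read_isogroup_table",
    "read_contig_table",
    "read_subject_lengths",
    "read_family_table",
    "read_species_map",
]


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


@dataclass(frozen=True)
class SeqRecord:
    """One sequence (read, assembly product, or protein)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid sequence id: {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


#: Newbler-style assembly product categories.
CATEGORIES = ("isotig", "contig", "singleton")


@dataclass(frozen=True)
class AssemblyProduct:
    """One assembly product with its Newbler-style group membership.

    Only isotigs carry an isogroup assignment and a contig membership list;
    contigs and singletons leave both unset.
    """

    id: str
    category: str
    seq: str
    isogroup_id: str | None = None
    contig_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category != "isotig" and (self.isogroup_id or self.contig_ids):
            raise ValueError(
                f"{self.id}: only isotigs carry isogroup/contig membership"
            )
        if len(self.seq) < 1:
            raise ValueError(f"{self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class BlastHit:
    """One row of 12-column tabular BLAST output.

    Coordinates are 1-based inclusive and normalized so start <= end; the
    original orientation is retained in ``q_strand`` / ``s_strand``
    (``"plus"`` or ``"minus"``).
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    q_strand: str = "plus"
    s_strand: str = "plus"

    def __post_init__(self) -> None:
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ValueError(f"{self.query_id}: interval not normalized")
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}: negative E-value")

    @property
    def subject_interval(self) -> tuple[int, int]:
        return (self.s_start, self.s_end)


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: str | Path, allow_empty_seq: bool = False) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord` in file order.

    Sequences are uppercased and line wrapping is removed. A record with an
    empty sequence raises :class:`FormatError` naming the record unless
    ``allow_empty_seq`` is set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[SeqRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq and not allow_empty_seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        out.append(SeqRecord(id=rec.id, seq=seq, description=rec.description))
    return out


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id
            desc = rec.description
            if desc and desc != rec.id and not desc.startswith(rec.id + " "):
                header = f"{rec.id} {desc}"
            elif desc and desc.startswith(rec.id + " "):
                header = desc
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Read FASTQ, discarding quality lines (qualities are never used)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return [
        SeqRecord(id=rec.id, seq=str(rec.seq).upper(), description=rec.description)
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def read_seqs(path: str | Path) -> list[SeqRecord]:
    """Read sequences from FASTA or FASTQ, sniffing on the first character."""
    path = Path(path)
    with path.open() as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path)
    return read_fasta(path)


# ---------------------------------------------------------------------------
# BLAST tabular

_N_COLUMNS = 12


def read_blast_tabular(path: str | Path) -> list[BlastHit]:
    """Parse 12-column tabular BLAST output into :class:`BlastHit` rows.

    Comment lines starting with '#' are skipped. Rows with a wrong column
    count or a non-numeric E-value raise :class:`FormatError` with the line
    number. Reversed coordinate pairs are normalized with the orientation
    recorded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    hits: list[BlastHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _N_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_N_COLUMNS} columns, got {len(cols)}"
                )
            try:
                q_start, q_end = int(cols[6]), int(cols[7])
                s_start, s_end = int(cols[8]), int(cols[9])
                evalue = float(cols[10])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            q_strand = "plus"
            if q_start > q_end:
                q_start, q_end, q_strand = q_end, q_start, "minus"
            s_strand = "plus"
            if s_start > s_end:
                s_start, s_end, s_strand = s_end, s_start, "minus"
            try:
                hits.append(
                    BlastHit(
                        query_id=cols[0],
                        subject_id=cols[1],
                        pct_identity=float(cols[2]),
                        aln_length=int(cols[3]),
                        mismatches=int(cols[4]),
                        gap_opens=int(cols[5]),
                        q_start=q_start,
                        q_end=q_end,
                        s_start=s_start,
                        s_end=s_end,
                        evalue=evalue,
                        bitscore=float(cols[11]),
                        q_strand=q_strand,
                        s_strand=s_strand,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return hits


def _fmt_float(x: float) -> str:
    # repr round-trips; strip a redundant trailing ".0" for integral values
    s = repr(x)
    return s[:-2] if s.endswith(".0") else s


def write_blast_tabular(hits: Iterable[BlastHit], path: str | Path) -> None:
    """Write hits back to 12-column tabular form, restoring orientation."""
    with Path(path).open("w") as fh:
        for h in hits:
            qs, qe = (h.q_end, h.q_start) if h.q_strand == "minus" else (h.q_start, h.q_end)
            ss, se = (h.s_end, h.s_start) if h.s_strand == "minus" else (h.s_start, h.s_end)
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        _fmt_float(h.pct_identity),
                        str(h.aln_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(qs),
                        str(qe),
                        str(ss),
                        str(se),
                        _fmt_float(h.evalue),
                        _fmt_float(h.bitscore),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Identifier conventions

_ISOTIG_RE = re.compile(r"^isotig\d+$")
_CONTIG_RE = re.compile(r"^contig\d+$")


def classify_product_id(product_id: str) -> str:
    """Classify a Newbler-style product id as isotig, contig, or singleton.

    Ids matching ``isotig<digits>`` / ``contig<digits>`` are isotigs/contigs;
    anything else (e.g. a raw 454 read accession like ``GAP9EXG06HFGHB``) is a
    singleton.
    """
    if not product_id:
        raise ValueError("empty product id")
    if _ISOTIG_RE.match(product_id):
        return "isotig"
    if _CONTIG_RE.match(product_id):
        return "contig"
    return "singleton"


def load_products(
    fasta_path: str | Path,
    isogroup_table: Mapping[str, str] | None = None,
    contig_table: Mapping[str, tuple[str, ...]] | None = None,
) -> list[AssemblyProduct]:
    """Build :class:`AssemblyProduct` objects from a product FASTA plus
    optional isotig→isogroup and isotig→contigs membership tables."""
    products = []
    for rec in read_fasta(fasta_path):
        category = classify_product_id(rec.id)
        isogroup = None
        contigs: tuple[str, ...] = ()
        if category == "isotig":
            if isogroup_table is not None:
                isogroup = isogroup_table.get(rec.id)
            if contig_table is not None:
                contigs = tuple(contig_table.get(rec.id, ()))
        products.append(
            AssemblyProduct(
                id=rec.id,
                category=category,
                seq=rec.seq,
                isogroup_id=isogroup,
                contig_ids=contigs,
            )
        )
    return products


# ---------------------------------------------------------------------------
# TSV tables (one-line header each)

def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def read_isogroup_table(path: str | Path) -> dict[str, str]:
    """isotig_id → isogroup_id."""
    df = _read_tsv(path, ("isotig_id", "isogroup_id"))
    return dict(zip(df["isotig_id"], df["isogroup_id"]))


def read_contig_table(path: str | Path) -> dict[str, tuple[str, ...]]:
    """isotig_id → tuple of member contig ids (comma-separated column)."""
    df = _read_tsv(path, ("isotig_id", "contig_ids"))
    return {
        isotig: tuple(c for c in contigs.split(",") if c)
        for isotig, contigs in zip(df["isotig_id"], df["contig_ids"])
    }


def read_subject_lengths(path: str | Path) -> dict[str, int]:
    """subject_id → subject length in amino acids."""
    df = _read_tsv(path, ("subject_id", "length_aa"))
    return {s: int(l) for s, l in zip(df["subject_id"], df["length_aa"])}


def read_family_table(path: str | Path) -> dict[str, frozenset[str]]:
    """family_id → set of reference subject ids (comma-separated column)."""
    df = _read_tsv(path, ("family_id", "subject_ids"))
    table: dict[str, frozenset[str]] = {}
    for fam, subjects in zip(df["family_id"], df["subject_ids"]):
        members = frozenset(s for s in subjects.split(",") if s)
        if not members:
            raise FormatError(f"family {fam!r} has no reference subjects")
        table[fam] = members
    return table


def read_species_map(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a subject/species/clade TSV into (subject→species, species→clade)."""
    df = _read_tsv(path, ("subject_id", "species", "clade"))
    subject_species = dict(zip(df["subject_id"], df["species"]))
    species_clade = dict(zip(df["species"], df["clade"]))
    return subject_species, species_clade
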