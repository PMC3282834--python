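"""Degenerate C2H2 zinc-finger motif scanning and six-frame translation.

The low-stringency C2H2 pattern used for read screening is

    X2 - C - X{1,2,4,5} - C - X12 - H - X{3-6} - (H or C)

where X positions accept any residue (including the unknown-residue code X)
but the four coordinating anchors must literally be C/H (the trailing
alternative allows a C2HC variant finger). Matches never span a stop codon.
Tandem fingers joined by the literal linker ``TGEKP`` are counted separately:
that linker is the classic signature of tandemly arrayed DNA-binding fingers.

Nucleotide sequences are screened by translating all six reading frames and
scanning each frame's peptide. The scanner itself is positional (no regular
expressions), reporting for each match start the shortest satisfying span.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as _iproduct
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .io import SeqRecord

__all__ = [
    "PatternSpec",
    "MotifSpec",
    "MotifMatch",
    "LOW_STRINGENCY",
    "translate_six_frames",
    "reverse_complement",
    "scan_c2h2",
    "find_tgekp_tandems",
    "filter_c2h2",
]


@dataclass(frozen=True)
class PatternSpec:
    """Structure of a degenerate C2H2 pattern.

    ``leading_x`` wildcards, then C, then a gap from ``gap1``, then C, a gap
    from ``gap2``, H, a gap from ``gap3``, and a final residue drawn from
    ``final``.
    """

    leading_x: int = 2
    gap1: tuple[int, ...] = (1, 2, 4, 5)
    gap2: tuple[int, ...] = (12,)
    gap3: tuple[int, ...] = (3, 4, 5, 6)
    final: str = "HC"

    def __post_init__(self) -> None:
        if not (self.gap1 and self.gap2 and self.gap3 and self.final):
            raise ValueError("gap sets and final alternatives must be nonempty")

    def combos(self) -> list[tuple[int, int, int]]:
        """Gap combinations ordered by total span length (shortest first)."""
        cs = list(_iproduct(self.gap1, self.gap2, self.gap3))
        cs.sort(key=lambda g: (sum(g), g))
        return cs

    def span_length(self, gaps: tuple[int, int, int]) -> int:
        return self.leading_x + 4 + sum(gaps)


#: The least stringent C2H2 definition: X2-C-X{1,2,4,5}-C-X12-H-X{3-6}-(H,C).
LOW_STRINGENCY = PatternSpec()


@dataclass(frozen=True)
class MotifSpec:
    """A named stringency level plus its pattern.

    Only the low-stringency pattern is built in; medium/high definitions are
    not published in a machine-readable form here, so they must be supplied
    as a :class:`PatternSpec` by the caller.
    """

    stringency: str = "low"
    pattern: PatternSpec | None = None

    def resolve(self) -> PatternSpec:
        if self.pattern is not None:
            return self.pattern
        if self.stringency == "low":
            return LOW_STRINGENCY
        raise ValueError(
            f"stringency {self.stringency!r} requires a configured pattern"
        )


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence; positions are 1-based inclusive in the peptide."""

    sequence_id: str
    frame: str
    start: int
    end: int
    matched_span: str


# ---------------------------------------------------------------------------
# Translation

_CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_NT = frozenset("ACGTN")

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate_frame(seq: str, offset: int) -> str:
    aas = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        # any N in the codon translates to the unknown residue X
        aas.append("X" if "N" in codon else _CODON_TO_AA[codon])
    return "".join(aas)


def translate_six_frames(seq: str) -> dict[str, str]:
    """Translate a nucleotide sequence in all six frames.

    Standard genetic code; stop codons become ``*``; codons containing N
    become X; trailing partial codons are dropped. Frames -1..-3 read the
    reverse complement.
    """
    seq = seq.upper()
    bad = set(seq) - _VALID_NT
    if bad:
        raise ValueError(f"non-IUPAC nucleotide characters: {sorted(bad)}")
    rc = reverse_complement(seq)
    return {
        "+1": _translate_frame(seq, 0),
        "+2": _translate_frame(seq, 1),
        "+3": _translate_frame(seq, 2),
        "-1": _translate_frame(rc, 0),
        "-2": _translate_frame(rc, 1),
        "-3": _translate_frame(rc, 2),
    }


# ---------------------------------------------------------------------------
# Scanning

def _match_at(
    peptide: str, i: int, pat: PatternSpec, combos: list[tuple[int, int, int]]
) -> tuple[int, int, int] | None:
    """Shortest gap combination matching at 0-based start i, or None."""
    n = len(peptide)
    # first anchor is always a literal C; reject cheaply before trying gaps
    if i + pat.leading_x >= n or peptide[i + pat.leading_x] != "C":
        return None
    for gaps in combos:
        g1, g2, g3 = gaps
        span = pat.span_length(gaps)
        if i + span > n:
            continue
        j = i
        window = peptide[j : j + span]
        if "*" in window:
            continue
        j += pat.leading_x
        if peptide[j] != "C":
            continue
        j += 1 + g1
        if peptide[j] != "C":
            continue
        j += 1 + g2
        if peptide[j] != "H":
            continue
        j += 1 + g3
        if peptide[j] not in pat.final:
            continue
        return gaps
    return None


def scan_c2h2(
    peptide: str,
    spec: MotifSpec = MotifSpec(),
    sequence_id: str = "",
    frame: str = "protein",
) -> list[MotifMatch]:
    """Find all C2H2 motif occurrences in a peptide.

    Every match start position is reported (overlapping matches allowed);
    for each start the shortest satisfying span is returned. Matches cannot
    span a stop codon, and the anchor positions require literal C/H (the
    unknown-residue code X only fills wildcard positions).
    """
    pat = spec.resolve()
    combos = pat.combos()
    matches = []
    for i in range(len(peptide)):
        gaps = _match_at(peptide, i, pat, combos)
        if gaps is None:
            continue
        span = pat.span_length(gaps)
        matches.append(
            MotifMatch(
                sequence_id=sequence_id,
                frame=frame,
                start=i + 1,
                end=i + span,
                matched_span=peptide[i : i + span],
            )
        )
    return matches


TGEKP = "TGEKP"


def find_tgekp_tandems(peptide: str, spec: MotifSpec = MotifSpec()) -> int:
    """Count ordered pairs of fingers joined by the literal TGEKP linker.

    A pair counts when the linker immediately follows the first match's end
    and a second match begins immediately after the linker.
    """
    matches = scan_c2h2(peptide, spec)
    starts = {m.start for m in matches}
    count = 0
    for m in matches:
        linker_start = m.end  # 0-based index of the residue after the match
        if peptide[linker_start : linker_start + len(TGEKP)] == TGEKP:
            if (m.end + len(TGEKP) + 1) in starts:
                count += 1
    return count


def filter_c2h2(
    records: Iterable[SeqRecord],
    spec: MotifSpec = MotifSpec(),
    mode: str = "nucleotide",
) -> tuple[list[SeqRecord], list[SeqRecord], dict]:
    """Partition records into (kept, removed) by motif presence.

    ``nucleotide`` mode removes a record if any of its six reading frames
    contains at least one motif; ``protein`` mode scans the sequence
    directly. The report carries removed/kept counts and the removed
    fraction.
    """
    if mode not in ("nucleotide", "protein"):
        raise ValueError(f"unknown mode {mode!r}")
    kept, removed = [], []
    for rec in records:
        if mode == "nucleotide":
            frames = translate_six_frames(rec.seq)
            has = any(
                scan_c2h2(pep, spec, rec.id, fr) for fr, pep in frames.items()
            )
        else:
            has = bool(scan_c2h2(rec.seq, spec, rec.id))
        (removed if has else kept).append(rec)
    total = len(kept) + len(removed)
    report = {
        "total": total,
        "kept": len(kept),
        "removed": len(removed),
        "removed_fraction": (len(removed) / total) if total else 0.0,
    }
    return kept, removed, report
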