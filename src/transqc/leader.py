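"""Splice-leader (SL) read screening.

Trans-spliced mRNAs carry a short leader sequence spliced onto their 5' end.
Reads carrying an SL are detected by windowed Hamming matching near the 5'
end (both the SL and its reverse complement, since 454 reads are unstranded)
and trimmed through the SL's 3' end; reads left shorter than a minimum
usable length are discarded. Trimming repeats until no SL occurrence remains
within the search window, so surviving reads are guaranteed SL-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .io import SeqRecord
from .motifs import reverse_complement

__all__ = ["LeaderParams", "ScreenResult", "screen_splice_leader", "find_leader"]


@dataclass(frozen=True)
class LeaderParams:
    """SL screening parameters.

    sl_sequences: the leader sequences to screen for (an input, never
        hardcoded — leaders are species-specific).
    max_mismatch: maximum Hamming mismatches for a hit (default 2).
    search_window: how far from the 5' end an SL may start, in bp.
    min_remaining: reads trimmed below this length are discarded (40 bp,
        the assembler's minimum usable read length).
    """

    sl_sequences: tuple[str, ...]
    max_mismatch: int = 2
    search_window: int = 100
    min_remaining: int = 40

    def __post_init__(self) -> None:
        if not self.sl_sequences:
            raise ValueError("sl_sequences must be nonempty")
        if self.min_remaining <= 0:
            raise ValueError("min_remaining must be positive")


@dataclass
class ScreenResult:
    kept: list[SeqRecord] = field(default_factory=list)
    trimmed: list[SeqRecord] = field(default_factory=list)
    discarded: list[SeqRecord] = field(default_factory=list)

    @property
    def report(self) -> dict:
        total = len(self.kept) + len(self.trimmed) + len(self.discarded)
        affected = len(self.trimmed) + len(self.discarded)
        return {
            "total": total,
            "kept": len(self.kept),
            "trimmed": len(self.trimmed),
            "discarded": len(self.discarded),
            "affected_fraction": (affected / total) if total else 0.0,
        }


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_leader(seq: str, params: LeaderParams) -> tuple[int, int] | None:
    """Best SL occurrence in the 5' window: (start, end) 0-based half-open.

    Both each SL and its reverse complement are tried. Best = fewest
    mismatches, ties broken leftmost, then by SL input order (forward before
    reverse complement). Returns None if nothing is within ``max_mismatch``.
    """
    candidates: list[str] = []
    for sl in params.sl_sequences:
        sl = sl.upper()
        candidates.append(sl)
        candidates.append(reverse_complement(sl))
    best: tuple[int, int, int, int] | None = None  # (mm, pos, cand_idx, end)
    for idx, sl in enumerate(candidates):
        L = len(sl)
        last = min(params.search_window - 1, len(seq) - L)
        for pos in range(0, last + 1):
            mm = _hamming(seq[pos : pos + L], sl)
            if mm <= params.max_mismatch:
                key = (mm, pos, idx, pos + L)
                if best is None or key < best:
                    best = key
    if best is None:
        return None
    return best[1], best[3]


def screen_splice_leader(
    records: Iterable[SeqRecord], params: LeaderParams
) -> ScreenResult:
    """Screen reads for splice leaders; trim or discard carriers.

    Each read is trimmed from its 5' end through the 3' end of the best SL
    occurrence, repeatedly, until no occurrence remains in the window. A
    read whose remainder falls below ``min_remaining`` is discarded. The
    three output lists partition the input exactly.
    """
    result = ScreenResult()
    for rec in records:
        seq = rec.seq
        trimmed_any = False
        while True:
            occ = find_leader(seq, params)
            if occ is None:
                break
            seq = seq[occ[1] :]
            trimmed_any = True
        if not trimmed_any:
            result.kept.append(rec)
        elif len(seq) < params.min_remaining:
            result.discarded.append(rec)
        else:
            result.trimmed.append(replace(rec, seq=seq))
    return result
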