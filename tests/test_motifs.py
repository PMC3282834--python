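"""Six-frame translation and C2H2 motif scanning."""

import re

import numpy as np
import pytest

from transqc.io import SeqRecord
from transqc.motifs import (
    MotifSpec,
    filter_c2h2,
    find_tgekp_tandems,
    reverse_complement,
    scan_c2h2,
    translate_six_frames,
)

#: Independent oracle for the low-stringency pattern
#: X2-C-X{1,2,4,5}-C-X12-H-X{3-6}-(H,C); lookahead allows overlapping starts.
C2H2_RE = re.compile(
    r"(?=([^*]{2}C(?:[^*]{1,2}|[^*]{4,5})C[^*]{12}H[^*]{3,6}[HC]))"
)

AA_WEIGHTED = list("ACDEFGHIKLMNPQRSTVWY" + "CH" * 4 + "*X")  # enrich anchors


def build_finger(g1=2, g3=3, wild="A", final="H"):
    return wild * 2 + "C" + wild * g1 + "C" + wild * 12 + "H" + wild * g3 + final


class TestTranslation:
    def test_standard_code_forward(self):
        assert translate_six_frames("ATGAAA")["+1"] == "MK"

    def test_reverse_frame_is_revcomp_translation(self):
        assert translate_six_frames("TTTCAT")["-1"] == "MK"

    def test_sub_codon_input_all_empty(self):
        assert all(p == "" for p in translate_six_frames("AT").values())

    def test_stop_and_n_handling(self):
        frames = translate_six_frames("TAANGG")
        assert frames["+1"] == "*X"

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            translate_six_frames("ACGU")

    def test_revcomp_swaps_frame_signs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            s = "".join(rng.choice(list("ACGT"), size=rng.integers(6, 120)))
            fwd = translate_six_frames(s)
            rev = translate_six_frames(reverse_complement(s))
            for k in ("1", "2", "3"):
                assert fwd[f"+{k}"] == rev[f"-{k}"]
                assert fwd[f"-{k}"] == rev[f"+{k}"]


class TestScan:
    def test_constructed_minimal_match(self):
        pep = "AACAACAAAAAAAAAAAAHAAAH"
        (m,) = scan_c2h2(pep)
        assert (m.start, m.end) == (1, 23)
        assert m.matched_span == pep

    def test_gap_of_three_between_cysteines_rejected(self):
        pep = "AAC" + "AAA" + "C" + "A" * 12 + "H" + "AAA" + "H"
        assert scan_c2h2(pep) == []

    def test_no_cysteine_no_match(self):
        assert scan_c2h2("A" * 50) == []

    def test_x_fills_wildcards_but_not_anchors(self):
        assert len(scan_c2h2("XXC" + "XX" + "C" + "X" * 12 + "H" + "XXX" + "H")) == 1
        # anchor replaced by X: no match
        assert scan_c2h2("XXX" + "XX" + "C" + "X" * 12 + "H" + "XXX" + "H") == []

    def test_match_cannot_span_stop(self):
        pep = "AAC" + "AA" + "C" + "A" * 6 + "*" + "A" * 5 + "H" + "AAA" + "H"
        assert scan_c2h2(pep) == []

    def test_shortest_span_reported_per_start(self):
        # both (g1=1, g3=4) and (g1=2, g3=3) fit here; total lengths equal,
        # but a case where g1=1 fails and g1=2 works must yield the short span
        wild = "A"
        pep = wild * 2 + "C" + "AD" + "C" + wild * 12 + "H" + "AAA" + "H" + "AAAA"
        (m,) = [x for x in scan_c2h2(pep) if x.start == 1]
        assert m.end - m.start + 1 == 23

    def test_agrees_with_regex_oracle_on_random_peptides(self):
        rng = np.random.default_rng(42)
        for _ in range(2000):
            pep = "".join(rng.choice(AA_WEIGHTED, size=int(rng.integers(10, 80))))
            mine = {m.start for m in scan_c2h2(pep)}
            oracle = {m.start() + 1 for m in C2H2_RE.finditer(pep)}
            assert mine == oracle, pep


class TestTandems:
    def test_no_motifs_no_tandems(self):
        assert find_tgekp_tandems("A" * 60) == 0

    def test_linked_pair_counts_once(self):
        pep = "DD" + build_finger() + "TGEKP" + build_finger() + "DD"
        assert find_tgekp_tandems(pep) == 1

    def test_single_substitution_in_linker_breaks_pair(self):
        pep = "DD" + build_finger() + "TGEKQ" + build_finger() + "DD"
        assert find_tgekp_tandems(pep) == 0


class TestFilter:
    def test_empty_input(self):
        kept, removed, report = filter_c2h2([])
        assert kept == [] and removed == []
        assert report["removed_fraction"] == 0.0

    def test_planted_motif_in_reverse_frame_detected(self):
        rng = np.random.default_rng(3)
        pep = build_finger()
        # encode peptide, then reverse-complement so the motif sits in frame -2
        codons = {"A": "GCT", "C": "TGT", "H": "CAT"}
        nt = "".join(codons[a] for a in pep)
        planted = reverse_complement("GG" + nt + "G")
        background = "".join(rng.choice(list("ACGT"), size=60))
        records = [
            SeqRecord(id="bg", seq=background),
            SeqRecord(id="hit", seq=planted),
        ]
        kept, removed, _ = filter_c2h2(records, mode="nucleotide")
        assert [r.id for r in removed] == ["hit"]

    def test_removed_fraction_equals_planted_fraction(self, small_bundle):
        b = small_bundle
        records = [SeqRecord(id=g.protein_id, seq=g.protein)
                   for g in b.truth.genes.values()]
        kept, removed, report = filter_c2h2(records, mode="protein")
        flagged = {g.protein_id for g in b.truth.genes.values() if g.motif}
        assert {r.id for r in removed} == flagged
        assert report["removed_fraction"] == pytest.approx(
            b.spec.motif_fraction
        )

    def test_filter_is_idempotent(self, small_bundle):
        records = [SeqRecord(id=g.protein_id, seq=g.protein)
                   for g in small_bundle.truth.genes.values()]
        kept, _, _ = filter_c2h2(records, mode="protein")
        kept2, removed2, _ = filter_c2h2(kept, mode="protein")
        assert kept2 == kept and removed2 == []

    def test_unknown_stringency_without_pattern_rejected(self):
        with pytest.raises(ValueError):
            scan_c2h2("ACDH", MotifSpec(stringency="high"))
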