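"""Unique-transcript deduplication: top-hit selection, overlap, grouping."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transqc.dedup import (
    DedupParams,
    TopHit,
    build_top_hits,
    count_unique,
    dedupe,
    interval_overlap_aa,
    select_top_hit,
)
from transqc.io import BlastHit


def make_hit(query="q1", subject="p1", evalue=1e-20, bitscore=100.0,
             s_start=1, s_end=50):
    return BlastHit(
        query_id=query, subject_id=subject, pct_identity=98.0,
        aln_length=s_end - s_start + 1, mismatches=0, gap_opens=0,
        q_start=1, q_end=150, s_start=s_start, s_end=s_end,
        evalue=evalue, bitscore=bitscore,
    )


def make_tophit(query, length, subject, interval):
    return TopHit(query_id=query, query_length=length, subject_id=subject,
                  subject_interval=interval, evalue=1e-30, bitscore=100.0)


PARAMS = DedupParams()


class TestTopHit:
    def test_minimum_evalue_dominates(self):
        hits = [make_hit(evalue=1e-5), make_hit(evalue=1e-30, subject="p2")]
        top = select_top_hit(hits, PARAMS, query_length=100)
        assert top.subject_id == "p2"

    def test_all_above_cutoff_gives_none(self):
        hits = [make_hit(evalue=1e-5), make_hit(evalue=1e-8)]
        assert select_top_hit(hits, PARAMS, 100) is None

    def test_empty_list_gives_none(self):
        assert select_top_hit([], PARAMS, 100) is None

    def test_tie_breaks_match_exhaustive_comparison(self):
        # oracle: best row under lexicographic (evalue, -bitscore, index)
        rows = [
            make_hit(subject="a", evalue=1e-20, bitscore=80),
            make_hit(subject="b", evalue=1e-20, bitscore=95),
            make_hit(subject="c", evalue=1e-20, bitscore=95),
        ]
        for perm in itertools.permutations(range(3)):
            hits = [rows[i] for i in perm]
            best = min(
                enumerate(hits), key=lambda ih: (ih[1].evalue, -ih[1].bitscore, ih[0])
            )[1]
            assert select_top_hit(hits, PARAMS, 100).subject_id == best.subject_id

    def test_multi_hsp_interval_from_highest_bitscore(self):
        hits = [
            make_hit(subject="p1", evalue=1e-40, bitscore=200, s_start=1, s_end=50),
            make_hit(subject="p1", evalue=1e-35, bitscore=250, s_start=80, s_end=160),
        ]
        top = select_top_hit(hits, PARAMS, 100)
        assert top.evalue == 1e-40
        assert top.subject_interval == (80, 160)

    def test_mixed_queries_rejected(self):
        with pytest.raises(ValueError):
            select_top_hit([make_hit("q1"), make_hit("q2")], PARAMS, 100)


class TestOverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [((1, 150), (160, 300), 0), ((1, 150), (140, 300), 11), ((1, 150), (100, 300), 51)],
    )
    def test_examples(self, a, b, expected):
        oracle = len(set(range(a[0], a[1] + 1)) & set(range(b[0], b[1] + 1)))
        assert oracle == expected
        assert interval_overlap_aa(a, b) == expected

    @settings(max_examples=300, deadline=None)
    @given(st.tuples(st.integers(1, 500), st.integers(1, 500)).map(sorted),
           st.tuples(st.integers(1, 500), st.integers(1, 500)).map(sorted))
    def test_matches_position_set_oracle(self, a, b):
        a, b = tuple(a), tuple(b)
        oracle = len(set(range(a[0], a[1] + 1)) & set(range(b[0], b[1] + 1)))
        assert interval_overlap_aa(a, b) == oracle
        assert interval_overlap_aa(a, b) == interval_overlap_aa(b, a)


class TestDedupe:
    def test_hand_traced_fragment_and_isoform_rule(self):
        q1 = make_tophit("q1", 600, "P", (1, 150))
        q2 = make_tophit("q2", 400, "P", (160, 300))
        groups = dedupe([q1, q2], PARAMS)
        assert len(groups) == 1
        g = groups[0]
        assert g.representative == "q1"
        assert g.fragments == ("q2",)  # overlap 0 <= 14

        q3 = make_tophit("q3", 500, "P", (100, 300))
        groups = dedupe([q1, q2, q3], PARAMS)
        g = groups[0]
        assert g.isoforms_or_paralogues == ("q3",)  # overlap 51 > 14
        assert g.fragments == ("q2",)

        q4 = make_tophit("q4", 300, "Q", (1, 80))
        groups = dedupe([q1, q2, q3, q4], PARAMS)
        assert count_unique(groups) == 2
        other = next(g for g in groups if g.subject_id == "Q")
        assert other.representative == "q4"
        assert other.fragments == () and other.isoforms_or_paralogues == ()

    def test_duplicate_query_rejected(self):
        q = make_tophit("q1", 100, "P", (1, 50))
        with pytest.raises(ValueError, match="q1"):
            dedupe([q, q], PARAMS)

    def test_boundary_overlap_exactly_14_is_fragment(self):
        rep = make_tophit("q1", 600, "P", (1, 150))
        edge = make_tophit("q2", 400, "P", (137, 300))  # overlap exactly 14
        g = dedupe([rep, edge], PARAMS)[0]
        assert g.fragments == ("q2",)
        over = make_tophit("q3", 400, "P", (136, 300))  # overlap 15
        g = dedupe([rep, over], PARAMS)[0]
        assert g.isoforms_or_paralogues == ("q3",)

    @settings(max_examples=60, deadline=None)
    @given(st.randoms(), st.integers(0, 2**20))
    def test_permutation_invariant_and_idempotent(self, rnd, _seed):
        tophits = [
            make_tophit(f"q{i}", 100 + (i * 37) % 400, f"P{i % 4}",
                        (1 + (i * 53) % 200, 1 + (i * 53) % 200 + 80))
            for i in range(12)
        ]
        shuffled = list(tophits)
        rnd.shuffle(shuffled)
        assert dedupe(shuffled, PARAMS) == dedupe(tophits, PARAMS)

    def test_raising_threshold_only_moves_isoforms_to_fragments(self):
        tophits = [
            make_tophit(f"q{i}", 500 - i, "P", (1 + 10 * i, 120 + 10 * i))
            for i in range(8)
        ]
        for lo, hi in [(0, 14), (14, 50), (50, 200)]:
            frag_lo = set(dedupe(tophits, DedupParams(overlap_threshold_aa=lo))[0].fragments)
            frag_hi = set(dedupe(tophits, DedupParams(overlap_threshold_aa=hi))[0].fragments)
            assert frag_lo <= frag_hi

    def test_count_bounded_by_queries_with_equality_iff_distinct_subjects(self):
        distinct = [make_tophit(f"q{i}", 100, f"P{i}", (1, 50)) for i in range(5)]
        assert count_unique(dedupe(distinct, PARAMS)) == 5
        shared = [make_tophit(f"q{i}", 100, f"P{i % 3}", (1, 50)) for i in range(5)]
        assert count_unique(dedupe(shared, PARAMS)) == 3 < 5

    def test_partition_additivity(self):
        """Deduplicating two query partitions with disjoint subject sets
        independently sums to the joint count."""
        part_a = [make_tophit(f"a{i}", 100, f"PA{i % 3}", (1, 60)) for i in range(6)]
        part_b = [make_tophit(f"b{i}", 100, f"PB{i % 4}", (1, 60)) for i in range(7)]
        joint = count_unique(dedupe(part_a + part_b, PARAMS))
        split = count_unique(dedupe(part_a, PARAMS)) + count_unique(dedupe(part_b, PARAMS))
        assert joint == split == 7


class TestSyntheticRecovery:
    def test_recovers_true_hit_bearing_gene_count(self, clean_bundle):
        b = clean_bundle
        lengths = {p.id: len(p.seq) for p in b.products}
        tophits = build_top_hits(b.hits, lengths, PARAMS)
        groups = dedupe(tophits, PARAMS)
        hit_products = {h.query_id for h in b.hits}
        true_genes = b.truth.hit_bearing_genes(hit_products)
        assert count_unique(groups) == len(true_genes)

    def test_decoys_do_not_change_the_count(self, small_bundle):
        b = small_bundle
        lengths = {p.id: len(p.seq) for p in b.products}
        groups = dedupe(build_top_hits(b.hits, lengths, PARAMS), PARAMS)
        true_genes = b.truth.hit_bearing_genes({h.query_id for h in b.hits})
        assert count_unique(groups) == len(true_genes)
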