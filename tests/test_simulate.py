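"""The ground-truth generator: determinism, planted truth, consistency."""

import filecmp

import pytest

from transqc.motifs import find_tgekp_tandems, scan_c2h2
from transqc.simulate import (
    TruthSpec,
    fragment_transcripts,
    generate_truth,
    simulate_blast,
    simulate_bundle,
    write_bundle,
)


class TestSpec:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            TruthSpec(motif_fraction=1.5)

    def test_family_sizes_bounded_by_genes(self):
        with pytest.raises(ValueError):
            TruthSpec(n_genes=3, families=(("f", 5),))


class TestTruth:
    def test_zero_genes_empty_truth(self):
        truth = generate_truth(TruthSpec(n_genes=0))
        assert truth.genes == {}

    def test_motif_flags_planted_and_detected_exactly(self):
        spec = TruthSpec(n_genes=200, seed=5, motif_fraction=0.1)
        truth = generate_truth(spec)
        flagged = [g for g in truth.genes.values() if g.motif]
        assert len(flagged) == 20
        for g in truth.genes.values():
            matches = scan_c2h2(g.protein)
            assert bool(matches) == g.motif
        tandem = [g for g in flagged if g.tandem]
        assert len(tandem) == 10  # half of flagged genes
        for g in tandem:
            assert find_tgekp_tandems(g.protein) >= 1

    def test_family_members_are_near_duplicates(self):
        spec = TruthSpec(n_genes=10, seed=2, families=(("fam", 4),))
        truth = generate_truth(spec)
        members = [g for g in truth.genes.values() if g.family_id == "fam"]
        assert len(members) == 4
        founder = members[0].protein
        for m in members[1:]:
            assert len(m.protein) == len(founder)
            diff = sum(a != b for a, b in zip(m.protein, founder))
            assert 0 < diff <= 0.2 * len(founder)

    def test_deterministic_byte_identical_outputs(self, tmp_path):
        spec = TruthSpec(n_genes=30, seed=9, motif_fraction=0.1,
                         sl_fraction=0.1, decoy_rate=0.1, no_hit_fraction=0.2)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        m1 = write_bundle(simulate_bundle(spec), d1)
        m2 = write_bundle(simulate_bundle(spec), d2)
        for name in m1:
            assert filecmp.cmp(m1[name], m2[name], shallow=False), name


class TestProducts:
    def test_spans_lie_within_protein_and_reads_map_back(self):
        spec = TruthSpec(n_genes=40, seed=4, sl_fraction=0.2)
        truth = generate_truth(spec)
        products, reads = fragment_transcripts(truth, spec)
        by_id = {p.id: p for p in products}
        for pid, pt in truth.products.items():
            protein = truth.genes[pt.gene_id].protein
            assert 1 <= pt.span[0] <= pt.span[1] <= len(protein)
            assert len(by_id[pid].seq) == 3 * (pt.span[1] - pt.span[0] + 1)
        for read in reads:
            pid = truth.reads[read.id]
            product = by_id[pid]
            sl = truth.genes[truth.products[pid].gene_id].sl
            body = read.seq[len(spec.sl_sequence):] if sl else read.seq
            assert body in product.seq
            if sl:
                assert read.seq.startswith(spec.sl_sequence)

    def test_same_gene_products_share_isogroup(self):
        spec = TruthSpec(n_genes=40, seed=6, singleton_fraction=0.0,
                         p_single_isoform=0.0)
        truth = generate_truth(spec)
        products, _ = fragment_transcripts(truth, spec)
        by_gene: dict[str, set] = {}
        for p in products:
            gene = truth.products[p.id].gene_id
            by_gene.setdefault(gene, set()).add(p.isogroup_id)
        assert all(len(groups) == 1 for groups in by_gene.values())

    def test_single_fragment_mode_one_isotig_per_transcript(self):
        spec = TruthSpec(n_genes=20, seed=8, p_single_isoform=1.0,
                         fragments_per_transcript=(1, 1), singleton_fraction=0.0)
        truth = generate_truth(spec)
        products, _ = fragment_transcripts(truth, spec)
        assert len(products) == 20
        assert all(p.category == "isotig" for p in products)


class TestBlastSimulation:
    def test_truth_passthrough_of_subject_coordinates(self, clean_bundle):
        b = clean_bundle
        for h in b.hits:
            pt = b.truth.products[h.query_id]
            assert (h.s_start, h.s_end) == pt.span
            assert h.subject_id == b.truth.genes[pt.gene_id].protein_id
            assert h.evalue <= 1e-10  # spans >= 60 aa always pass the cutoff

    def test_no_hit_fraction_exact(self):
        spec = TruthSpec(n_genes=100, seed=12, no_hit_fraction=0.7,
                         p_single_isoform=1.0, fragments_per_transcript=(1, 1))
        truth = generate_truth(spec)
        products, _ = fragment_transcripts(truth, spec)
        hits, _ = simulate_blast(products, truth, spec)
        with_hit = {h.query_id for h in hits}
        assert len(products) - len(with_hit) == 70

    def test_decoys_are_strictly_worse(self):
        spec = TruthSpec(n_genes=30, seed=13, decoy_rate=1.0)
        b = simulate_bundle(spec)
        by_query: dict[str, list] = {}
        for h in b.hits:
            by_query.setdefault(h.query_id, []).append(h)
        decoy_seen = False
        for query, hits in by_query.items():
            true_subject = b.truth.genes[b.truth.products[query].gene_id].protein_id
            top = min(hits, key=lambda h: (h.evalue, -h.bitscore))
            assert top.subject_id == true_subject
            decoy_seen = decoy_seen or len(hits) > 1
        assert decoy_seen
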