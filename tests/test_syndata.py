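import numpy as np
import pytest

from solnc import syndata
from solnc.genomic_io import spliced_sequence
from solnc.syndata import SimulationConfig

from conftest import dummy_truth, make_dummy_records


class TestGenome:
    def test_seed_determinism_byte_identical(self):
        cfg = SimulationConfig(seed=1, n_chromosomes=2, chrom_length=150_000,
                               n_coding_genes=20)
        s1, a1 = syndata.generate_genome(cfg)
        s2, a2 = syndata.generate_genome(cfg)
        assert s1 == s2
        assert a1.genes == a2.genes
        assert a1.transcripts == a2.transcripts

    def test_no_genes_gives_background_only(self):
        cfg = SimulationConfig(n_coding_genes=0, n_chromosomes=1, chrom_length=50_000)
        seqs, ann = syndata.generate_genome(cfg)
        assert ann.genes == {}
        assert len(seqs["chr01"]) == 50_000

    def test_background_gc_close_to_requested(self):
        cfg = SimulationConfig(
            n_coding_genes=0, n_chromosomes=1, chrom_length=1_000_000,
            gc_background=0.35, seed=3,
        )
        seqs, _ = syndata.generate_genome(cfg)
        s = seqs["chr01"]
        gc = (s.count("G") + s.count("C")) / len(s)
        assert 0.33 <= gc <= 0.37

    def test_genes_do_not_overlap(self, sim_bundle):
        ann = sim_bundle["annotation"]
        by_chrom = {}
        for g in ann.genes.values():
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 >= e1

    def test_placement_failure_names_constraint(self):
        cfg = SimulationConfig(n_chromosomes=1, chrom_length=20_000, n_coding_genes=50)
        with pytest.raises(ValueError, match="cannot place"):
            syndata.generate_genome(cfg)


class TestTranscriptSet:
    def test_class_counts_zero_emits_only_mrnas(self):
        cfg = SimulationConfig(
            n_chromosomes=1, chrom_length=200_000, n_coding_genes=20,
            class_counts={"intergenic": 0, "antisense": 0, "sense": 0,
                          "bidirectional": 0, "other": 0},
        )
        seqs, ann = syndata.generate_genome(cfg)
        recs, truth = syndata.generate_transcript_set(seqs, ann, cfg)
        assert len(recs) == 20
        assert truth.transcripts["true_coding"].all()

    def test_intergenic_only_far_from_all_genes(self):
        cfg = SimulationConfig(
            n_chromosomes=1, chrom_length=400_000, n_coding_genes=20,
            class_counts={"intergenic": 50, "antisense": 0, "sense": 0,
                          "bidirectional": 0, "other": 0},
        )
        seqs, ann = syndata.generate_genome(cfg)
        recs, truth = syndata.generate_transcript_set(seqs, ann, cfg)
        lncs = [r for r in recs if not truth.transcripts.loc[r.id, "true_coding"]]
        assert len(lncs) == 50
        for r in lncs:
            for g in ann.genes.values():
                gap = max(g.start - r.end, r.start - g.end)
                assert gap > cfg.bidirectional_window

    def test_lengths_and_exon_structure(self, sim_bundle):
        truth = sim_bundle["truth"]
        recs = [
            r for r in sim_bundle["records"]
            if not truth.transcripts.loc[r.id, "true_coding"]
        ]
        lengths = np.array([r.length for r in recs])
        assert lengths.min() >= 201
        assert (lengths < 2000).mean() >= 0.90
        single = np.mean([r.exon_count == 1 for r in recs])
        assert single > 0.5  # most lncRNAs single-exon

    def test_sequences_consistent_with_genome(self, sim_bundle):
        genome = sim_bundle["sequences"]
        for r in sim_bundle["records"][::25]:
            assert spliced_sequence(genome, r) == r.sequence


class TestCounts:
    def test_de_fraction_zero_gives_empty_truth(self):
        cfg = SimulationConfig(de_fraction=0.0, seed=5)
        recs = make_dummy_records(100)
        truth = dummy_truth(recs)
        syndata.generate_count_matrix(recs, truth, cfg)
        assert len(truth.de) == 0

    def test_zero_dispersion_uses_poisson_branch(self, rng):
        draws = syndata.nb_draws(rng, 50.0, 0.0, size=20_000)
        # Poisson: variance equals mean
        assert abs(draws.var() / draws.mean() - 1.0) < 0.05

    def test_nb_moments_match_within_ten_percent(self, rng):
        mu, alpha = 100.0, 0.05
        draws = syndata.nb_draws(rng, mu, alpha, size=10_000)
        expected_var = mu + alpha * mu**2
        assert abs(draws.mean() - mu) / mu < 0.1
        assert abs(draws.var() - expected_var) / expected_var < 0.1

    def test_planted_fold_changes_have_exact_magnitude(self, sim_bundle):
        truth = sim_bundle["truth"]
        fc = truth.de["true_log2fc"].abs()
        assert (fc == sim_bundle["config"].de_log2fc).all()

    def test_counts_deterministic_for_seed(self):
        cfg = SimulationConfig(seed=9)
        recs = make_dummy_records(50)
        m1 = syndata.generate_count_matrix(recs, dummy_truth(recs), cfg)
        m2 = syndata.generate_count_matrix(recs, dummy_truth(recs), cfg)
        assert (m1.counts.values == m2.counts.values).all()


class TestMirnaPlanting:
    def test_planted_precursor_identity_recoverable(self, sim_bundle):
        from solnc import mirna
        truth = sim_bundle["truth"]
        by_id = {r.id: r for r in sim_bundle["records"]}
        for row in truth.mirna_precursors.itertuples():
            hit = mirna.precursor_similarity(
                row.mirna_id, sim_bundle["mirnas"][row.mirna_id],
                row.lncrna_id, by_id[row.lncrna_id].sequence,
            )
            assert hit is not None
            assert hit.identity >= row.identity - 1e-9

    def test_planted_target_sites_score_zero(self, sim_bundle):
        from solnc import mirna
        truth = sim_bundle["truth"]
        by_gene = {r.gene_id: r for r in sim_bundle["records"] if r.gene_id}
        for row in truth.mirna_targets.itertuples():
            hits = mirna.mirna_target_sites(
                row.mirna_id, sim_bundle["mirnas"][row.mirna_id],
                row.gene_id, by_gene[row.gene_id].sequence,
            )
            assert any(h.penalty == 0.0 for h in hits)

    def test_no_mirnas_requested(self):
        cfg = SimulationConfig(
            n_mirnas=0, n_planted_precursors=0, n_planted_mirna_targets=0, seed=4,
            n_chromosomes=1, chrom_length=300_000, n_coding_genes=20,
            class_counts={"intergenic": 20, "antisense": 0, "sense": 0,
                          "bidirectional": 0, "other": 0},
        )
        seqs, ann = syndata.generate_genome(cfg)
        recs, truth = syndata.generate_transcript_set(seqs, ann, cfg)
        syndata.generate_count_matrix(recs, truth, cfg)
        mirnas, _ = syndata.generate_mirna_set(seqs, recs, truth, cfg)
        assert mirnas == {}
        assert len(truth.mirna_precursors) == 0


class TestQpcrPanel:
    def test_noise_free_panel_recovers_expression_ratio(self):
        cfg = SimulationConfig(qpcr_sigma=0.0, seed=21)
        seqs, ann = syndata.generate_genome(cfg)
        recs, truth = syndata.generate_transcript_set(seqs, ann, cfg)
        matrix = syndata.generate_count_matrix(recs, truth, cfg)
        panel = syndata.generate_qpcr_panel(matrix, recs, truth, cfg)
        from solnc import qpcr
        rq = qpcr.relative_quantity(panel)
        norm = matrix.counts.div(truth.size_factors, axis=1)
        hp = [l for l in norm.columns if l.startswith("HP-BR")]
        lp = [l for l in norm.columns if l.startswith("LP-BR")]
        lp_rows = rq[(rq["condition"] == "LP-BR") & (rq["transcript"] != panel.reference)]
        for row in lp_rows.itertuples():
            expected = np.log2(norm.loc[row.transcript, lp]).mean() - \
                np.log2(norm.loc[row.transcript, hp]).mean()
            assert np.log2(row.rq) == pytest.approx(expected, abs=1e-9)

    def test_zero_expression_selection_rejected(self, sim_bundle):
        matrix = sim_bundle["matrix"]
        zero_id = matrix.counts.index[0]
        matrix2 = type(matrix)(counts=matrix.counts.copy(), samples=matrix.samples)
        matrix2.counts.loc[zero_id] = 0
        with pytest.raises(ValueError, match="zero normalized expression"):
            syndata.generate_qpcr_panel(
                matrix2, sim_bundle["records"], sim_bundle["truth"],
                sim_bundle["config"], transcript_ids=[zero_id],
            )


def test_annotation_map_and_labels_cover_coding_genes(sim_bundle):
    cfg, ann = sim_bundle["config"], sim_bundle["annotation"]
    amap = syndata.generate_annotation_map(ann, cfg)
    assert set(amap["gene_id"]) == set(ann.coding_genes())
    assert set(amap["category"]) <= {"BP", "MF", "CC", "KEGG"}
    labels = syndata.generate_interest_labels(ann, cfg)
    assert set(labels.values()) <= {"TF", "P_related", "hormone"}
    assert set(labels) <= set(ann.coding_genes())
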