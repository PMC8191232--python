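import math

import numpy as np
import pytest

from solnc import classify
from solnc.classify import ClassifiedLncRNA, classify_lncrna, classify_all
from solnc.genomic_io import Gene, GenomeAnnotation, Transcript, TranscriptRecord


def _ann(genes, transcripts):
    return GenomeAnnotation(
        genes={g.id: g for g in genes},
        transcripts={t.id: t for t in transcripts},
    )


def _gene(gid, start, end, strand, exons=None, chrom="c1"):
    g = Gene(id=gid, chrom=chrom, strand=strand, start=start, end=end)
    t = Transcript(
        id=f"{gid}.1", gene_id=gid, chrom=chrom, strand=strand,
        exons=tuple(exons) if exons else ((start, end),),
    )
    return g, t


def _lnc(start, end, strand, exons=None, chrom="c1"):
    ex = tuple(exons) if exons else ((start, end),)
    return TranscriptRecord(
        id="lnc", chrom=chrom, strand=strand, exons=ex,
        sequence="A" * sum(e - s for s, e in ex),
    )


class TestRules:
    def test_exonic_same_strand_overlap_is_sense(self):
        g, t = _gene("g1", 1000, 3000, "+", exons=[(1000, 1500), (2500, 3000)])
        ann = _ann([g], [t])
        res = classify_lncrna(_lnc(1400, 1800, "+"), ann)
        assert res.lnc_class == "sense"
        assert res.distance == 0

    def test_intronic_opposite_strand_is_antisense(self):
        g, t = _gene("g1", 1000, 3000, "+", exons=[(1000, 1500), (2500, 3000)])
        ann = _ann([g], [t])
        res = classify_lncrna(_lnc(1600, 2200, "-"), ann)
        assert res.lnc_class == "antisense"

    def test_intronic_same_strand_is_other(self):
        g, t = _gene("g1", 1000, 3000, "+", exons=[(1000, 1500), (2500, 3000)])
        ann = _ann([g], [t])
        res = classify_lncrna(_lnc(1600, 2200, "+"), ann)
        assert res.lnc_class == "other"

    def test_divergent_upstream_of_minus_gene_is_bidirectional(self):
        # lncRNA on + strand starting 300 bp beyond a − gene's TSS (its end)
        g, t = _gene("g1", 1000, 3000, "-")
        ann = _ann([g], [t])
        res = classify_lncrna(_lnc(3300, 3800, "+"), ann)
        assert res.lnc_class == "bidirectional"
        assert res.distance == 301  # TSS-to-TSS

    def test_far_gene_is_intergenic(self):
        g, t = _gene("g1", 1000, 3000, "+")
        ann = _ann([g], [t])
        res = classify_lncrna(_lnc(53_000, 53_500, "+"), ann)
        assert res.lnc_class == "intergenic"
        assert res.distance == 50_000

    def test_convergent_neighbor_is_not_bidirectional(self):
        # gene on + strand, lncRNA upstream on + strand: tandem, not divergent
        g, t = _gene("g1", 5000, 8000, "+")
        ann = _ann([g], [t])
        res = classify_lncrna(_lnc(4200, 4700, "+"), ann)
        assert res.lnc_class == "intergenic"

    def test_unknown_chromosome_flagged_intergenic_infinite(self):
        g, t = _gene("g1", 0, 100, "+")
        ann = _ann([g], [t])
        res = classify_lncrna(_lnc(10, 300, "+", chrom="chrZZ"), ann)
        assert res.lnc_class == "intergenic"
        assert math.isinf(res.distance)


class TestSummary:
    def _classified(self, counts):
        out = []
        k = 0
        for cls, n in counts.items():
            for _ in range(n):
                rec = TranscriptRecord(
                    id=f"x{k}", chrom="c1", strand="+", exons=((0, 10),),
                    sequence="ACGTACGTAC",
                )
                out.append(ClassifiedLncRNA(rec, cls, None, 0))
                k += 1
        return out

    def test_reported_class_split_arithmetic(self):
        counts = {"intergenic": 2865, "bidirectional": 454, "antisense": 498,
                  "sense": 121, "other": 228}
        summary = classify.summarize_classes(self._classified(counts))
        assert summary.total == 4166
        assert summary.percentages["intergenic"] == 68.77
        assert summary.genic_count == 1301
        assert summary.genic_percentage == 31.23

    def test_single_class_is_hundred_percent(self):
        summary = classify.summarize_classes(self._classified({"sense": 7}))
        assert summary.percentages["sense"] == 100.0

    def test_percentages_sum_to_hundred(self):
        counts = {"intergenic": 3, "antisense": 5, "sense": 7, "bidirectional": 11,
                  "other": 13}
        summary = classify.summarize_classes(self._classified(counts))
        assert sum(summary.percentages.values()) == pytest.approx(100, abs=0.011)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            classify.summarize_classes([])


class TestDescriptiveStats:
    def test_all_gc_sequence(self):
        rec = TranscriptRecord(id="x", chrom="c", strand="+", exons=((0, 10),),
                               sequence="G" * 10)
        stats = classify.descriptive_stats([ClassifiedLncRNA(rec, "sense", None, 0)])
        assert stats["gc_max"] == 1.0

    def test_length_threshold_fraction(self):
        recs = [
            TranscriptRecord(id=f"a{i}", chrom="c", strand="+", exons=((0, 1000),),
                             sequence="A" * 1000)
            for i in range(100)
        ] + [
            TranscriptRecord(id=f"b{i}", chrom="c", strand="+", exons=((0, 3000),),
                             sequence="A" * 3000)
            for i in range(5)
        ]
        classified = [ClassifiedLncRNA(r, "intergenic", None, 1) for r in recs]
        stats = classify.descriptive_stats(classified, length_threshold=2000)
        assert stats["fraction_below_threshold"] == pytest.approx(100 / 105, abs=1e-6)

    def test_single_exon_histogram(self):
        rec = TranscriptRecord(id="x", chrom="c", strand="+", exons=((0, 10),),
                               sequence="A" * 10)
        stats = classify.descriptive_stats([ClassifiedLncRNA(rec, "sense", None, 0)])
        assert stats["exon_histogram"] == {1: 1}


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def oracle_classify(record, annotation, window=1000):
    """All-pairs re-statement of the class definitions, kept independent of
    the indexed implementation."""
    genes = [g for g in annotation.genes.values() if g.chrom == record.chrom]
    if not genes:
        return "intergenic"
    exons_by_gene = {}
    for t in annotation.transcripts.values():
        exons_by_gene.setdefault(t.gene_id, []).extend(
            (s, e, t.strand) for s, e in t.exons
        )

    def span_overlap(g):
        return g.start < record.end and g.end > record.start

    def exonic(g):
        for s, e, strand in exons_by_gene.get(g.id, []):
            if strand != record.strand:
                continue
            for ls, le in record.exons:
                if ls < e and le > s:
                    return True
        return False

    if any(span_overlap(g) and exonic(g) for g in genes):
        return "sense"
    if any(span_overlap(g) and g.strand != record.strand for g in genes):
        return "antisense"
    if any(span_overlap(g) and g.strand == record.strand for g in genes):
        return "other"
    rec_tss = record.start if record.strand == "+" else record.end - 1
    for g in genes:
        g_tss = g.start if g.strand == "+" else g.end - 1
        if g.strand == record.strand:
            continue
        divergent = rec_tss >= g_tss if record.strand == "+" else rec_tss <= g_tss
        if divergent and abs(rec_tss - g_tss) <= window:
            return "bidirectional"
    return "intergenic"


def _random_layout(rng, n_genes=8):
    genes, transcripts = [], []
    pos = int(rng.integers(0, 500))
    for i in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 4))
        exons, p = [], pos
        for k in range(n_ex):
            el = int(rng.integers(100, 800))
            exons.append((p, p + el))
            p += el + (int(rng.integers(50, 1500)) if k < n_ex - 1 else 0)
        g = Gene(id=f"g{i:02d}", chrom="c1", strand=strand, start=exons[0][0],
                 end=exons[-1][1])
        genes.append(g)
        transcripts.append(
            Transcript(id=f"g{i:02d}.1", gene_id=g.id, chrom="c1", strand=strand,
                       exons=tuple(exons))
        )
        pos = exons[-1][1] + int(rng.integers(0, 2500))
    return _ann(genes, transcripts)


def test_indexed_classifier_equals_bruteforce_on_random_layouts(rng):
    for layout in range(100):
        ann = _random_layout(rng)
        limit = max(g.end for g in ann.genes.values()) + 3000
        for _ in range(10):
            start = int(rng.integers(0, limit))
            length = int(rng.integers(201, 2000))
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(1, 3))
            if n_ex == 1:
                exons = ((start, start + length),)
            else:
                half = length // 2
                gap = int(rng.integers(50, 500))
                exons = ((start, start + half),
                         (start + half + gap, start + length + gap))
            rec = TranscriptRecord(
                id="lnc", chrom="c1", strand=strand, exons=exons,
                sequence="A" * sum(e - s for s, e in exons),
            )
            expected = oracle_classify(rec, ann)
            got = classify_lncrna(rec, ann).lnc_class
            assert got == expected, (layout, rec.exons, strand, expected, got)


def test_roundtrip_matches_generator_truth(sim_bundle):
    truth = sim_bundle["truth"]
    lncs = [
        r for r in sim_bundle["records"]
        if not truth.transcripts.loc[r.id, "true_coding"]
    ]
    assert len(lncs) >= 500
    classified = classify_all(lncs, sim_bundle["annotation"],
                              sim_bundle["config"].bidirectional_window)
    for c in classified:
        assert c.lnc_class == truth.true_class(c.id)
    assert {c.lnc_class for c in classified} == set(classify.CLASSES)
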