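"""Positional classification of lncRNAs against a coding annotation.

Five mutually exclusive classes, assigned by precedence:

1. ``sense`` — ≥1 bp exon-to-exon overlap with a coding transcript on the
   same strand;
2. ``antisense`` — any overlap with a coding gene span on the opposite strand;
3. ``other`` — same-strand overlap with a gene span but no exonic overlap
   (i.e. intronic, same strand);
4. ``bidirectional`` — no gene overlap, transcription start within
   ``bidirectional_window`` of a coding gene's start in divergent
   (head-to-head) orientation;
5. ``intergenic`` — everything else.

Ties within a rule are broken by smallest distance, then lexicographic
gene id, so classification is deterministic.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genomic_io import GenomeAnnotation, Gene, TranscriptRecord

CLASSES = ("intergenic", "antisense", "sense", "bidirectional", "other")


@dataclass
class ClassifiedLncRNA:
    record: TranscriptRecord
    lnc_class: str
    nearest_gene: str | None
    distance: float  # bp; 0 if overlapping; inf if no gene on the chromosome

    @property
    def id(self) -> str:
        return self.record.id


@dataclass
class ClassSummary:
    counts: dict[str, int]
    percentages: dict[str, float]
    total: int
    per_chromosome: dict[str, int]
    exon_histogram: dict[int, int]
    gc_mean: float
    gc_min: float
    gc_max: float
    length_histogram: dict[str, int]

    @property
    def genic_count(self) -> int:
        return self.total - self.counts.get("intergenic", 0)

    @property
    def genic_percentage(self) -> float:
        return round(100 * self.genic_count / self.total, 2)


class GeneIndex:
    """Per-chromosome sorted gene-span index for fast overlap/nearest queries."""

    def __init__(self, annotation: GenomeAnnotation):
        self._by_chrom: dict[str, list[Gene]] = {}
        self._starts: dict[str, list[int]] = {}
        self._max_len: dict[str, int] = {}
        self._exons: dict[str, list[tuple[int, int, str]]] = {}  # gene -> exon ivs + strand
        coding = annotation.coding_genes()
        for g in coding.values():
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, genes in self._by_chrom.items():
            genes.sort(key=lambda g: (g.start, g.id))
            self._starts[chrom] = [g.start for g in genes]
            self._max_len[chrom] = max(g.end - g.start for g in genes)
        for t in annotation.transcripts.values():
            if t.gene_id in coding:
                self._exons.setdefault(t.gene_id, []).extend(
                    (s, e, t.strand) for s, e in t.exons
                )

    def chromosomes(self) -> set[str]:
        return set(self._by_chrom)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Gene]:
        """Genes whose span intersects [start, end)."""
        genes = self._by_chrom.get(chrom)
        if not genes:
            return []
        starts = self._starts[chrom]
        lo = bisect_left(starts, start - self._max_len[chrom])
        hi = bisect_right(starts, end)
        return [g for g in genes[lo:hi] if g.start < end and g.end > start]

    def near(self, chrom: str, start: int, end: int, margin: int) -> list[Gene]:
        """Genes whose span comes within ``margin`` bp of [start, end)."""
        return self.overlapping(chrom, start - margin, end + margin)

    def all_on(self, chrom: str) -> list[Gene]:
        return self._by_chrom.get(chrom, [])

    def exons_of(self, gene_id: str) -> list[tuple[int, int, str]]:
        return self._exons.get(gene_id, [])


def _exonic_overlap(record: TranscriptRecord, index: GeneIndex, gene: Gene) -> bool:
    """≥1 bp overlap between lncRNA exons and the gene's transcript exons on
    the lncRNA's own strand."""
    for gs, ge, gstrand in index.exons_of(gene.id):
        if gstrand != record.strand:
            continue
        for s, e in record.exons:
            if s < ge and e > gs:
                return True
    return False


def _span_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two half-open spans (0 if adjacent, overlap -> 0)."""
    if a_start < b_end and a_end > b_start:
        return 0
    if a_end <= b_start:
        return b_start - a_end
    return a_start - b_end


def _gene_tss(g: Gene) -> int:
    return g.start if g.strand == "+" else g.end - 1


def _divergent(record: TranscriptRecord, gene: Gene) -> bool:
    """Head-to-head orientation: promoters adjacent, transcribing apart."""
    if record.strand == gene.strand:
        return False
    if record.strand == "+":
        # lncRNA runs right, gene runs left: lncRNA must start at/after gene TSS
        return record.tss >= _gene_tss(gene)
    return record.tss <= _gene_tss(gene)


def classify_lncrna(
    record: TranscriptRecord,
    annotation: GenomeAnnotation,
    bidirectional_window: int = 1000,
    index: GeneIndex | None = None,
) -> ClassifiedLncRNA:
    """Assign one of the five positional classes to a single lncRNA."""
    if index is None:
        index = GeneIndex(annotation)
    if record.chrom not in index.chromosomes():
        return ClassifiedLncRNA(record, "intergenic", None, math.inf)

    overlapping = index.overlapping(record.chrom, record.start, record.end)

    def pick(genes: Iterable[Gene], key) -> Gene:
        return min(genes, key=lambda g: (key(g), g.id))

    sense_hits = [g for g in overlapping if _exonic_overlap(record, index, g)]
    if sense_hits:
        return ClassifiedLncRNA(record, "sense", pick(sense_hits, lambda g: 0).id, 0)
    anti_hits = [g for g in overlapping if g.strand != record.strand]
    if anti_hits:
        return ClassifiedLncRNA(record, "antisense", pick(anti_hits, lambda g: 0).id, 0)
    other_hits = [g for g in overlapping if g.strand == record.strand]
    if other_hits:
        return ClassifiedLncRNA(record, "other", pick(other_hits, lambda g: 0).id, 0)

    nearby = index.near(record.chrom, record.start, record.end, bidirectional_window + 1)
    divergent = [
        g for g in nearby
        if _divergent(record, g) and abs(record.tss - _gene_tss(g)) <= bidirectional_window
    ]
    if divergent:
        dist = lambda g: abs(record.tss - _gene_tss(g))
        best = pick(divergent, dist)
        return ClassifiedLncRNA(record, "bidirectional", best.id, dist(best))

    genes = index.all_on(record.chrom)
    gap = lambda g: _span_gap(record.start, record.end, g.start, g.end)
    best = pick(genes, gap)
    return ClassifiedLncRNA(record, "intergenic", best.id, gap(best))


def classify_all(
    records: Sequence[TranscriptRecord],
    annotation: GenomeAnnotation,
    bidirectional_window: int = 1000,
) -> list[ClassifiedLncRNA]:
    index = GeneIndex(annotation)
    return [classify_lncrna(r, annotation, bidirectional_window, index) for r in records]


def summarize_classes(classified: Sequence[ClassifiedLncRNA]) -> ClassSummary:
    """Counts, percentages (2 decimals) and descriptive distributions."""
    if not classified:
        raise ValueError("cannot summarize an empty classified set")
    counts = {c: 0 for c in CLASSES}
    for c in classified:
        counts[c.lnc_class] = counts.get(c.lnc_class, 0) + 1
    total = len(classified)
    percentages = {c: round(100 * n / total, 2) for c, n in counts.items()}
    per_chrom = Counter(c.record.chrom for c in classified)
    exon_hist = Counter(c.record.exon_count for c in classified)
    gcs = np.array([c.record.gc_fraction for c in classified])
    lengths = np.array([c.record.length for c in classified])
    bins = [(0, 500), (500, 1000), (1000, 2000), (2000, 4000), (4000, np.inf)]
    length_hist = {
        f"{lo}-{hi if np.isfinite(hi) else 'inf'}": int(((lengths >= lo) & (lengths < hi)).sum())
        for lo, hi in bins
    }
    return ClassSummary(
        counts=counts,
        percentages=percentages,
        total=total,
        per_chromosome=dict(sorted(per_chrom.items())),
        exon_histogram=dict(sorted(exon_hist.items())),
        gc_mean=float(gcs.mean()),
        gc_min=float(gcs.min()),
        gc_max=float(gcs.max()),
        length_histogram=length_hist,
    )


def descriptive_stats(
    classified: Sequence[ClassifiedLncRNA], length_threshold: int = 2000
) -> dict:
    """GC range/mean, fraction below a length threshold, exon histogram."""
    records = [c.record for c in classified]
    if not records:
        return {
            "gc_min": float("nan"), "gc_max": float("nan"), "gc_mean": float("nan"),
            "fraction_below_threshold": float("nan"), "exon_histogram": {},
        }
    gcs = np.array([r.gc_fraction for r in records])
    lengths = np.array([r.length for r in records])
    return {
        "gc_min": float(gcs.min()),
        "gc_max": float(gcs.max()),
        "gc_mean": float(gcs.mean()),
        "fraction_below_threshold": float((lengths < length_threshold).mean()),
        "exon_histogram": dict(sorted(Counter(r.exon_count for r in records).items())),
    }


def summary_frame(summary: ClassSummary) -> pd.DataFrame:
    """Class counts/percentages as a tidy frame for export."""
    return pd.DataFrame(
        {
            "class": list(summary.counts),
            "count": [summary.counts[c] for c in summary.counts],
            "percentage": [summary.percentages[c] for c in summary.counts],
        }
    )
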