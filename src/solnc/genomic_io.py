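"""Readers/writers and core containers for every format the pipeline touches.

All coordinates are 0-based half-open in memory.  GTF on disk is 1-based
inclusive; the conversion happens only at the GTF boundary, nowhere else.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Gene:
    id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open span
    end: int
    biotype: str = "protein_coding"


@dataclass(frozen=True)
class Transcript:
    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start site coordinate (last base for − strand)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GenomeAnnotation:
    """Protein-coding gene/transcript/exon intervals, the classification frame.

    ``genes`` may be empty for a bag of assembled transcript models.
    """

    genes: dict[str, Gene] = field(default_factory=dict)
    transcripts: dict[str, Transcript] = field(default_factory=dict)
    chrom_lengths: dict[str, int] | None = None

    def validate(self) -> None:
        for t in self.transcripts.values():
            if t.strand not in "+-":
                raise ValueError(f"transcript {t.id}: strand must be + or -")
            exons = t.exons
            if not exons:
                raise ValueError(f"transcript {t.id}: no exons")
            for s, e in exons:
                if e <= s:
                    raise ValueError(f"transcript {t.id}: empty/inverted exon {s}-{e}")
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 < e1:
                    raise ValueError(f"transcript {t.id}: exons overlap or unsorted")
            if self.chrom_lengths is not None and t.chrom in self.chrom_lengths:
                if t.end > self.chrom_lengths[t.chrom]:
                    raise ValueError(
                        f"transcript {t.id}: exon end {t.end} beyond chromosome "
                        f"{t.chrom} length {self.chrom_lengths[t.chrom]}"
                    )
        for g in self.genes.values():
            if g.strand not in "+-":
                raise ValueError(f"gene {g.id}: strand must be + or -")
            if g.end <= g.start:
                raise ValueError(f"gene {g.id}: empty/inverted span")

    def coding_genes(self) -> dict[str, Gene]:
        return {i: g for i, g in self.genes.items() if g.biotype == "protein_coding"}

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]


@dataclass
class TranscriptRecord:
    """An assembled transcript: structure plus its spliced sequence."""

    id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    sequence: str
    gene_id: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def gc_fraction(self) -> float:
        return gc_fraction(self.sequence)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def validate(self) -> None:
        total = sum(e - s for s, e in self.exons)
        if total != len(self.sequence):
            raise ValueError(
                f"transcript {self.id}: exon span {total} != sequence length {len(self.sequence)}"
            )


def spliced_sequence(genome: Mapping[str, str], t: Transcript | TranscriptRecord) -> str:
    """Extract the spliced transcript sequence from chromosome sequences."""
    chrom = genome[t.chrom]
    seq = "".join(chrom[s:e] for s, e in t.exons)
    return revcomp(seq) if t.strand == "-" else seq


@dataclass
class ExpressionMatrix:
    """Transcript × sample raw counts plus the sample design factors."""

    counts: pd.DataFrame  # index transcript ids, columns sample labels, int
    samples: pd.DataFrame  # index sample label; columns genotype, treatment, replicate

    def validate(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample labels in count matrix")
        if (self.counts.values < 0).any():
            bad = self.counts.stack()
            bad = bad[bad < 0].index[0]
            raise ValueError(f"negative count at transcript {bad[0]}, sample {bad[1]}")
        missing = set(self.samples.index) - set(self.counts.columns)
        if missing:
            raise ValueError(f"metadata labels without count column: {sorted(missing)}")
        extra = set(self.counts.columns) - set(self.samples.index)
        if extra:
            raise ValueError(f"count columns without metadata: {sorted(extra)}")

    def labels_for(self, genotype: str | None = None, treatment: str | None = None) -> list[str]:
        sel = self.samples
        if genotype is not None:
            sel = sel[sel["genotype"] == genotype]
        if treatment is not None:
            sel = sel[sel["treatment"] == treatment]
        return list(sel.index)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_GTF_COLUMNS = 9


def _parse_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise ValueError(f"GTF line {lineno}: malformed attribute {chunk!r}")
        key, value = chunk.split(" ", 1)
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path, chrom_lengths: Mapping[str, int] | None = None) -> GenomeAnnotation:
    """Parse a GTF file into a :class:`GenomeAnnotation`.

    Disk coordinates are 1-based inclusive; they come out 0-based half-open.
    Features used: ``gene``, ``transcript``, ``exon``.  Strand "." is rejected
    (classification needs orientation).
    """
    genes: dict[str, Gene] = {}
    exons: dict[str, list[Interval]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}  # id -> (gene_id, chrom, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != _GTF_COLUMNS:
                raise ValueError(f"GTF line {lineno}: expected 9 columns, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"GTF line {lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise ValueError(f"GTF line {lineno}: end {end1} < start {start1}")
            if strand not in "+-":
                raise ValueError(f"GTF line {lineno}: strand {strand!r} not allowed")
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _parse_attributes(attr_s, lineno)
            if feature == "gene":
                gid = attrs.get("gene_id")
                if gid is None:
                    raise ValueError(f"GTF line {lineno}: gene feature missing gene_id")
                genes[gid] = Gene(
                    id=gid,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    biotype=attrs.get("gene_biotype", "protein_coding"),
                )
            elif feature in ("transcript", "exon"):
                tid = attrs.get("transcript_id")
                if tid is None:
                    raise ValueError(f"GTF line {lineno}: missing transcript_id attribute")
                gid = attrs.get("gene_id", tid)
                prev = tx_meta.get(tid)
                if prev is not None and prev != (gid, chrom, strand):
                    raise ValueError(f"GTF line {lineno}: inconsistent transcript {tid}")
                tx_meta[tid] = (gid, chrom, strand)
                if feature == "exon":
                    exons.setdefault(tid, []).append((start, end))
    transcripts: dict[str, Transcript] = {}
    for tid, (gid, chrom, strand) in tx_meta.items():
        ex = sorted(exons.get(tid, []))
        if not ex:
            raise ValueError(f"transcript {tid}: no exon features")
        transcripts[tid] = Transcript(id=tid, gene_id=gid, chrom=chrom, strand=strand, exons=tuple(ex))
    ann = GenomeAnnotation(
        genes=genes,
        transcripts=transcripts,
        chrom_lengths=dict(chrom_lengths) if chrom_lengths else None,
    )
    ann.validate()
    return ann


def write_gtf(ann: GenomeAnnotation, path: str | Path, source: str = "solnc", header: str | None = None) -> None:
    """Write annotation as GTF (1-based inclusive on disk)."""

    def attr_str(pairs: list[tuple[str, str]]) -> str:
        return " ".join(f'{k} "{v}";' for k, v in pairs)

    lines: list[str] = []
    if header:
        lines.append(f"# {header}")
    for gid in sorted(ann.genes):
        g = ann.genes[gid]
        lines.append(
            "\t".join(
                [g.chrom, source, "gene", str(g.start + 1), str(g.end), ".", g.strand, ".",
                 attr_str([("gene_id", g.id), ("gene_biotype", g.biotype)])]
            )
        )
    for tid in sorted(ann.transcripts):
        t = ann.transcripts[tid]
        base = [("gene_id", t.gene_id), ("transcript_id", t.id)]
        lines.append(
            "\t".join(
                [t.chrom, source, "transcript", str(t.start + 1), str(t.end), ".", t.strand, ".",
                 attr_str(base)]
            )
        )
        for s, e in t.exons:
            lines.append(
                "\t".join(
                    [t.chrom, source, "exon", str(s + 1), str(e), ".", t.strand, ".", attr_str(base)]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA → {id: uppercase sequence}. Duplicate identifiers are an error."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA identifier {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Counts + metadata TSV
# ---------------------------------------------------------------------------


def read_counts(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read a transcript × sample count TSV and its sample metadata TSV.

    Counts must be non-negative integers; every column must be described in the
    metadata and vice versa.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    for col in raw.columns:
        for tid, value in raw[col].items():
            fv = float(value)
            if fv < 0 or fv != int(fv):
                raise ValueError(
                    f"count for transcript {tid}, sample {col} is {value!r}: "
                    "must be a non-negative integer"
                )
    counts = raw.astype(int)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, comment="#")
    meta.index = meta.index.astype(str)
    matrix = ExpressionMatrix(counts=counts, samples=meta)
    matrix.validate()
    return matrix


def write_counts(matrix: ExpressionMatrix, path: str | Path, metadata_path: str | Path,
                 header: str | None = None) -> None:
    for target, frame in ((path, matrix.counts), (metadata_path, matrix.samples)):
        with open(target, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            frame.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------


def write_network(network: nx.DiGraph, path: str | Path, format: str = "graphml") -> None:
    """Export an interaction network as GraphML or a TSV edge list.

    GraphML keeps node attributes (node_type, interest_label) and the edge
    attribute edge_type; the TSV has columns source, target, edge_type.
    """
    if format == "graphml":
        g = network.copy()
        for _n, data in g.nodes(data=True):
            data.setdefault("node_type", "mRNA")
            data.setdefault("interest_label", "none")
        for _u, _v, data in g.edges(data=True):
            data.setdefault("edge_type", "unknown")
        nx.write_graphml(g, str(path), named_key_ids=True)
    elif format == "tsv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["source", "target", "edge_type"])
            for u, v, data in sorted(network.edges(data=True)):
                writer.writerow([u, v, data.get("edge_type", "unknown")])
    else:
        raise ValueError(f"unknown network format {format!r} (use graphml or tsv)")


def read_network_tsv(path: str | Path) -> list[tuple[str, str, str]]:
    """Read back a TSV edge list as (source, target, edge_type) tuples."""
    edges: list[tuple[str, str, str]] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:3] != ["source", "target", "edge_type"]:
            raise ValueError(f"unexpected edge-list header {header}")
        for row in reader:
            if row:
                edges.append((row[0], row[1], row[2]))
    return edges
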