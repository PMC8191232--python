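"""Synthetic-data generator: every pipeline input with known ground truth.

Emulates the study design the pipeline is built for: 12 libraries from two
soybean genotypes (BR = Bogao, NR = NN94156) under high (HP, 500 µM) and low
(LP, 5 µM) phosphate with 3 biological replicates; a gene-sparse
multi-chromosome genome; lncRNAs of five positional classes (~35 % GC,
mostly single-exon, ≥90 % shorter than 2 kb); NB-distributed counts with
planted differential expression; planted miRNA precursors and target sites;
and Ct panels derived from expression.

Placement is done so that the classify module's class definitions hold by
construction, which makes the classifier round-trip a definitional test.
Genic lncRNAs are transcribed off the generated genome (introns, or an
intron/exon edge for the sense class) so chromosome FASTA, transcript FASTA
and mRNA sequences always stay mutually consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import identify
from .genomic_io import (
    ExpressionMatrix,
    Gene,
    GenomeAnnotation,
    Transcript,
    TranscriptRecord,
    revcomp,
    spliced_sequence,
)
from .qpcr import CtPanel

GENOTYPES = ("BR", "NR")  # Bogao (P-sensitive), NN94156 (P-tolerant)
TREATMENTS = ("HP", "LP")  # 500 µM vs 5 µM phosphate

P_RELATED_FAMILIES = (
    "miR399", "miR827", "miR395", "miR319", "miR156",
    "miR159", "miR166", "miR169", "miR398", "miR447",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_design() -> tuple[tuple[str, str, int], ...]:
    return tuple(
        (g, t, r) for t in TREATMENTS for g in GENOTYPES for r in (1, 2, 3)
    )


def sample_label(genotype: str, treatment: str, replicate: int) -> str:
    return f"{treatment}-{genotype}-{replicate}"


@dataclass
class SimulationConfig:
    n_chromosomes: int = 4
    chrom_length: int = 600_000
    n_coding_genes: int = 200
    # Fig-1a-style class mix at 1/7 scale: 595 lncRNAs total
    class_counts: dict[str, int] = field(
        default_factory=lambda: {
            "intergenic": 409, "antisense": 71, "bidirectional": 65,
            "other": 33, "sense": 17,
        }
    )
    gc_background: float = 0.35
    design: tuple[tuple[str, str, int], ...] = field(default_factory=default_design)
    base_mean_log_mu: float = math.log(150.0)
    base_mean_log_sigma: float = 1.2
    base_mean_min: float = 0.0  # truncation floor for baseline means (0 = none)
    dispersion: float = 0.05
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    n_mirnas: int = 10
    n_planted_precursors: int = 5
    n_planted_mirna_targets: int = 9
    qpcr_n_transcripts: int = 14
    qpcr_sigma: float = 0.2
    qpcr_intercept: float = 32.0
    bidirectional_window: int = 1000
    seed: int = 2020

    def validate(self) -> None:
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class_counts must be non-negative")
        unknown = set(self.class_counts) - {
            "intergenic", "antisense", "sense", "bidirectional", "other"
        }
        if unknown:
            raise ValueError(f"unknown lncRNA classes {sorted(unknown)}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.de_log2fc <= 0:
            raise ValueError("de_log2fc must be > 0")
        if not 0 < self.gc_background < 1:
            raise ValueError("gc_background must be in (0, 1)")
        labels = [sample_label(*d) for d in self.design]
        if len(set(labels)) != len(labels):
            raise ValueError("design contains duplicate sample labels")
        for g, t, _r in self.design:
            if g not in GENOTYPES or t not in TREATMENTS:
                raise ValueError(f"invalid design cell ({g}, {t})")

    @property
    def sample_labels(self) -> list[str]:
        return [sample_label(*d) for d in self.design]


@dataclass
class TruthTable:
    """Ground truth emitted alongside the synthetic data."""

    transcripts: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: transcript, contrast, true_log2fc (only non-null effects)
    de: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["transcript", "contrast", "true_log2fc"])
    )
    size_factors: pd.Series = field(default_factory=pd.Series)
    mirna_precursors: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["mirna_id", "lncrna_id", "identity"])
    )
    mirna_targets: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["mirna_id", "gene_id"])
    )
    shared_targets: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "lncrna_id", "mirna_id"])
    )

    def lncrna_ids(self) -> list[str]:
        t = self.transcripts
        return list(t.index[~t["true_coding"]])

    def true_class(self, transcript_id: str) -> str:
        return self.transcripts.loc[transcript_id, "true_class"]

    def de_ids(self, contrast: str | None = None) -> set[str]:
        de = self.de
        if contrast is not None:
            de = de[de["contrast"] == contrast]
        return set(de["transcript"])


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _seq_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def nb_draws(
    rng: np.random.Generator, mean: np.ndarray | float, alpha: float, size=None
) -> np.ndarray:
    """NB(mean, dispersion alpha) draws; alpha = 0 is the Poisson limit."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

_EXON_COUNT_P = np.array([0.30, 0.22, 0.16, 0.12, 0.09, 0.06, 0.05])


def _sample_codons(rng: np.random.Generator, n: int) -> str:
    probs = identify.codon_probabilities(include_stops=False)
    codons = sorted(probs)
    p = np.array([probs[c] for c in codons])
    return "".join(np.array(codons)[rng.choice(len(codons), size=n, p=p / p.sum())])


def _sample_stop(rng: np.random.Generator) -> str:
    weights = np.array([identify.CODON_FREQUENCIES[c] for c in identify.STOP_CODONS])
    return identify.STOP_CODONS[rng.choice(3, p=weights / weights.sum())]


def _split_lengths(rng: np.random.Generator, total: int, parts: int, minimum: int) -> list[int]:
    """Random composition of ``total`` into ``parts`` parts, each ≥ minimum."""
    if parts * minimum > total:
        parts = max(1, total // minimum)
    if parts == 1:
        return [total]
    extra = total - parts * minimum
    cuts = np.sort(rng.integers(0, extra + 1, size=parts - 1))
    sizes = np.diff(np.concatenate([[0], cuts, [extra]]))
    return [minimum + int(s) for s in sizes]


def generate_genome(config: SimulationConfig) -> tuple[dict[str, str], GenomeAnnotation]:
    """Background chromosomes with non-overlapping coding genes stamped in.

    Gene CDS codons come from the fixed codon-usage table shared with the
    identify module; UTRs and intergenic space use the background nucleotide
    model at ``gc_background``.  Deterministic for a fixed seed.
    """
    config.validate()
    rng = _rng(config, 0)
    chrom_names = [f"chr{i + 1:02d}" for i in range(config.n_chromosomes)]
    chroms = {
        name: _background(rng, config.chrom_length, config.gc_background)
        for name in chrom_names
    }

    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    per_chrom = [config.n_coding_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_coding_genes % config.n_chromosomes):
        per_chrom[i] += 1

    min_gap = 2500
    gene_no = 0
    for ci, chrom in enumerate(chrom_names):
        n_genes = per_chrom[ci]
        if n_genes == 0:
            continue
        # build gene structures first, then distribute the leftover as gaps
        structures = []
        for _ in range(n_genes):
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = 1 + int(rng.choice(7, p=_EXON_COUNT_P))
            utr5 = _seq_str(_background(rng, int(rng.integers(60, 150)), config.gc_background))
            n_codons = int(rng.integers(100, 400))
            cds = "ATG" + _sample_codons(rng, n_codons) + _sample_stop(rng)
            utr3 = _seq_str(_background(rng, int(rng.integers(100, 300)), config.gc_background))
            tx_seq = utr5 + cds + utr3
            exon_lens = _split_lengths(rng, len(tx_seq), n_exons, 60)
            n_exons = len(exon_lens)
            intron_lens: list[int] = []
            if n_exons > 1:
                long_idx = int(rng.integers(0, n_exons - 1))
                for k in range(n_exons - 1):
                    if k == long_idx:
                        intron_lens.append(int(rng.integers(1500, 3500)))
                    else:
                        intron_lens.append(int(rng.integers(100, 600)))
            span = len(tx_seq) + sum(intron_lens)
            structures.append((strand, tx_seq, exon_lens, intron_lens, span))
        total_span = sum(s[4] for s in structures)
        leftover = config.chrom_length - total_span - (n_genes + 1) * min_gap
        if leftover < 0:
            raise ValueError(
                f"cannot place {n_genes} genes on {chrom}: total gene span "
                f"{total_span} plus minimum gaps exceeds chromosome length "
                f"{config.chrom_length}"
            )
        gaps = min_gap + np.floor(rng.dirichlet(np.ones(n_genes + 1)) * leftover).astype(int)
        pos = int(gaps[0])
        for gi, (strand, tx_seq, exon_lens, intron_lens, span) in enumerate(structures):
            # region laid out in transcript orientation, then flipped for '-'
            pieces: list[str] = []
            rel_exons: list[tuple[int, int]] = []
            off = 0
            for k, el in enumerate(exon_lens):
                start_tx = sum(exon_lens[:k])
                pieces.append(tx_seq[start_tx:start_tx + el])
                rel_exons.append((off, off + el))
                off += el
                if k < len(intron_lens):
                    pieces.append(
                        _seq_str(_background(rng, intron_lens[k], config.gc_background))
                    )
                    off += intron_lens[k]
            region = "".join(pieces)
            if strand == "-":
                region = revcomp(region)
                L = len(region)
                rel_exons = sorted((L - e, L - s) for s, e in rel_exons)
            arr = np.frombuffer(region.encode(), dtype=np.uint8)
            chroms[chrom][pos:pos + span] = arr
            gene_no += 1
            gid = f"G{ci + 1:02d}g{gene_no:04d}"
            tid = f"{gid}.1"
            exons = tuple((pos + s, pos + e) for s, e in rel_exons)
            genes[gid] = Gene(id=gid, chrom=chrom, strand=strand, start=pos, end=pos + span)
            transcripts[tid] = Transcript(
                id=tid, gene_id=gid, chrom=chrom, strand=strand, exons=exons
            )
            pos += span + int(gaps[gi + 1])

    sequences = {name: _seq_str(arr) for name, arr in chroms.items()}
    ann = GenomeAnnotation(
        genes=genes,
        transcripts=transcripts,
        chrom_lengths={name: config.chrom_length for name in chrom_names},
    )
    ann.validate()
    return sequences, ann


# ---------------------------------------------------------------------------
# transcript set
# ---------------------------------------------------------------------------


def _lncrna_length(rng: np.random.Generator) -> int:
    """Log-normal truncated to [201, 4000] nt (≥90 % below 2 kb)."""
    while True:
        length = int(round(math.exp(rng.normal(math.log(480.0), 0.7))))
        if 201 <= length <= 4000:
            return length


def _introns_of(t: Transcript) -> list[tuple[int, int]]:
    return [(e1, s2) for (_s1, e1), (s2, _e2) in zip(t.exons, t.exons[1:])]


class _GapAllocator:
    """Tracks free intergenic intervals per chromosome and sub-allocates."""

    def __init__(self, annotation: GenomeAnnotation, chrom_length: int):
        self.free: dict[str, list[tuple[int, int]]] = {}
        assert annotation.chrom_lengths is not None
        for chrom, clen in annotation.chrom_lengths.items():
            spans = sorted(
                (g.start, g.end) for g in annotation.genes.values() if g.chrom == chrom
            )
            gaps = []
            cursor = 0
            for s, e in spans:
                if s > cursor:
                    gaps.append((cursor, s))
                cursor = max(cursor, e)
            if cursor < clen:
                gaps.append((cursor, clen))
            self.free[chrom] = gaps

    def take(self, chrom: str, start: int, end: int) -> bool:
        """Reserve [start, end) if it lies inside one free interval."""
        for i, (s, e) in enumerate(self.free[chrom]):
            if s <= start and end <= e:
                pieces = []
                if start > s:
                    pieces.append((s, start))
                if end < e:
                    pieces.append((end, e))
                self.free[chrom][i:i + 1] = pieces
                return True
        return False

    def random_fit(
        self, rng: np.random.Generator, length: int, margin: int
    ) -> tuple[str, int] | None:
        """A random position with ``margin`` clearance inside some free gap."""
        candidates = [
            (chrom, s, e)
            for chrom, gaps in self.free.items()
            for (s, e) in gaps
            if e - s >= length + 2 * margin
        ]
        if not candidates:
            return None
        weights = np.array([e - s - length - 2 * margin + 1 for _c, s, e in candidates], float)
        idx = int(rng.choice(len(candidates), p=weights / weights.sum()))
        chrom, s, e = candidates[idx]
        start = int(rng.integers(s + margin, e - margin - length + 1))
        if self.take(chrom, start, start + length):
            return chrom, start
        return None


def generate_transcript_set(
    sequences: Mapping[str, str],
    annotation: GenomeAnnotation,
    config: SimulationConfig,
) -> tuple[list[TranscriptRecord], TruthTable]:
    """Coding mRNAs (one per gene) plus lncRNAs per ``class_counts``.

    Placement satisfies the positional class definitions by construction:
    sense lncRNAs straddle an intron/exon boundary on the gene's strand,
    antisense and "other" lncRNAs sit inside introns (opposite / same
    strand), bidirectional lncRNAs start within the divergent-promoter
    window of a gene's TSS without overlap, and intergenic lncRNAs keep more
    than the window's distance from every gene span.
    """
    config.validate()
    rng = _rng(config, 1)
    records: list[TranscriptRecord] = []
    truth_rows: list[tuple[str, str, bool]] = []

    for tid in sorted(annotation.transcripts):
        t = annotation.transcripts[tid]
        rec = TranscriptRecord(
            id=tid, chrom=t.chrom, strand=t.strand, exons=t.exons,
            sequence=spliced_sequence(sequences, t), gene_id=t.gene_id,
        )
        records.append(rec)
        truth_rows.append((tid, "mRNA", True))

    genes_sorted = [annotation.genes[g] for g in sorted(annotation.genes)]
    window = config.bidirectional_window
    alloc = _GapAllocator(annotation, config.chrom_length)

    # intron inventory: (gene, intron interval, next exon interval or None)
    intron_pool: list[tuple[Gene, tuple[int, int], tuple[int, int] | None]] = []
    for g in genes_sorted:
        for t in annotation.transcripts_of(g.id):
            for iv in _introns_of(t):
                nxt = next(((s, e) for s, e in t.exons if s == iv[1]), None)
                intron_pool.append((g, iv, nxt))
    rng.shuffle(intron_pool)
    intron_used = [False] * len(intron_pool)

    def claim_intron(min_len: int) -> int | None:
        for i, used in enumerate(intron_used):
            if used:
                continue
            s, e = intron_pool[i][1]
            if e - s >= min_len:
                return i
        return None

    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"TCONS_{counter:08d}"

    def add_lncrna(chrom: str, strand: str, exons: tuple[tuple[int, int], ...], cls: str):
        rec = TranscriptRecord(
            id=next_id(), chrom=chrom, strand=strand, exons=exons,
            sequence=spliced_sequence(sequences, TranscriptRecord(
                id="", chrom=chrom, strand=strand, exons=exons, sequence="")),
        )
        records.append(rec)
        truth_rows.append((rec.id, cls, False))

    def multi_exon(chrom_start: int, length: int, rng) -> tuple[tuple[int, int], ...]:
        """Split a spliced length into 1-3 exons with small introns."""
        if rng.random() >= 0.2 or length < 160:
            return ((chrom_start, chrom_start + length),)
        n_ex = 2 if rng.random() < 0.7 else 3
        exon_lens = _split_lengths(rng, length, n_ex, 50)
        intron_lens = [int(rng.integers(60, 250)) for _ in range(len(exon_lens) - 1)]
        exons = []
        pos = chrom_start
        for k, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if k < len(intron_lens):
                pos += intron_lens[k]
        return tuple(exons)

    order = ("sense", "other", "antisense", "bidirectional", "intergenic")
    for cls in order:
        want = config.class_counts.get(cls, 0)
        for _n in range(want):
            if cls in ("antisense", "other"):
                length = _lncrna_length(rng)
                idx = claim_intron(min(length, 2800) + 4)
                if idx is None:
                    raise ValueError(
                        f"class {cls} impossible: no free intron can host a lncRNA "
                        "(increase gene count or intron lengths)"
                    )
                g, (is_, ie), _nxt = intron_pool[idx]
                intron_used[idx] = True
                length = min(length, ie - is_ - 4)
                start = is_ + 2
                strand = g.strand if cls == "other" else ("-" if g.strand == "+" else "+")
                add_lncrna(g.chrom, strand, ((start, start + length),), cls)
            elif cls == "sense":
                length = _lncrna_length(rng)
                idx = None
                for i, used in enumerate(intron_used):
                    if used or intron_pool[i][2] is None:
                        continue
                    _g, (is_, ie), nxt = intron_pool[i]
                    if ie - is_ >= 180 and nxt[1] - nxt[0] >= 70:
                        idx = i
                        break
                if idx is None:
                    raise ValueError(
                        "class sense impossible: no intron/exon junction available"
                    )
                g, (is_, ie), nxt = intron_pool[idx]
                intron_used[idx] = True
                ov = int(rng.integers(25, min(61, nxt[1] - nxt[0] - 5)))
                length = min(length, (ie - is_ - 4) + ov)
                start = ie - (length - ov)
                add_lncrna(g.chrom, g.strand, ((start, start + length),), cls)
            elif cls == "bidirectional":
                placed = False
                for _try in range(200):
                    g = genes_sorted[int(rng.integers(0, len(genes_sorted)))]
                    length = _lncrna_length(rng)
                    d = int(rng.integers(2, 200))
                    if g.strand == "+":
                        exons = multi_exon(0, length, rng)  # layout relative, shift below
                        span = exons[-1][1]
                        end = g.start - d
                        start = end - span
                        exons = tuple((start + s, start + e) for s, e in exons)
                        strand = "-"
                    else:
                        start = g.end + d
                        exons = multi_exon(start, length, rng)
                        strand = "+"
                        span = exons[-1][1] - start
                        end = exons[-1][1]
                    lo, hi = exons[0][0], exons[-1][1]
                    if lo < 0 or hi > config.chrom_length:
                        continue
                    # TSS-to-TSS distance must stay inside the window
                    tss_l = lo if strand == "+" else hi - 1
                    tss_g = g.start if g.strand == "+" else g.end - 1
                    if abs(tss_l - tss_g) > window:
                        continue
                    if alloc.take(g.chrom, lo, hi):
                        add_lncrna(g.chrom, strand, exons, cls)
                        placed = True
                        break
                if not placed:
                    raise ValueError(
                        "class bidirectional impossible: no upstream room near any TSS"
                    )
            else:  # intergenic
                placed = False
                for _try in range(200):
                    length = _lncrna_length(rng)
                    exons_rel = multi_exon(0, length, rng)
                    span = exons_rel[-1][1]
                    fit = alloc.random_fit(rng, span, margin=window + 2)
                    if fit is None:
                        continue
                    chrom, start = fit
                    exons = tuple((start + s, start + e) for s, e in exons_rel)
                    strand = "+" if rng.random() < 0.5 else "-"
                    add_lncrna(chrom, strand, exons, cls)
                    placed = True
                    break
                if not placed:
                    raise ValueError(
                        "class intergenic impossible: no gap with window clearance left"
                    )

    truth = TruthTable(
        transcripts=pd.DataFrame(
            truth_rows, columns=["transcript", "true_class", "true_coding"]
        ).set_index("transcript")
    )
    return records, truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def _condition_effect(
    genotype: str, treatment: str, beta: float, geno_effect: float, treat_geno: str
) -> float:
    eff = 0.0
    if genotype == treat_geno and treatment == "LP":
        eff += beta
    if genotype == "NR":
        eff += geno_effect
    return eff


def generate_count_matrix(
    transcripts: Sequence[TranscriptRecord],
    truth: TruthTable,
    config: SimulationConfig,
) -> ExpressionMatrix:
    """NB counts with planted DE and log-uniform size factors.

    counts_ij ~ NB(mean = s_j · μ_i · 2^effect, dispersion α); planted
    treatment effects (±de_log2fc) apply to the LP samples of one genotype
    (BR when present), planted genotype effects to the NR samples; a
    transcript carries at most one of the two, so every non-null true
    contrast effect has magnitude exactly de_log2fc.
    """
    config.validate()
    rng = _rng(config, 2)
    ids = [t.id for t in transcripts]
    n = len(ids)
    labels = config.sample_labels

    mu = np.exp(rng.normal(config.base_mean_log_mu, config.base_mean_log_sigma, size=n))
    if config.base_mean_min > 0:
        low = mu < config.base_mean_min
        while low.any():
            mu[low] = np.exp(
                rng.normal(config.base_mean_log_mu, config.base_mean_log_sigma, size=int(low.sum()))
            )
            low = mu < config.base_mean_min

    genotypes = sorted({g for g, _t, _r in config.design})
    treatments = sorted({t for _g, t, _r in config.design})
    treat_geno = "BR" if "BR" in genotypes else genotypes[0]

    beta = np.zeros(n)
    geno_effect = np.zeros(n)
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    both_axes = len(genotypes) > 1 and len(treatments) > 1
    if len(treatments) > 1:
        n_treat = (n_de + 1) // 2 if both_axes else n_de
    else:
        n_treat = 0
    signs = rng.choice([-1.0, 1.0], size=n_de)
    for k, i in enumerate(de_idx):
        if k < n_treat:
            beta[i] = signs[k] * config.de_log2fc
        else:
            geno_effect[i] = signs[k] * config.de_log2fc

    s = np.exp(rng.uniform(math.log(0.5), math.log(2.0), size=len(labels)))
    counts = np.zeros((n, len(labels)), dtype=np.int64)
    for j, (g, t, _r) in enumerate(config.design):
        eff = np.array(
            [_condition_effect(g, t, beta[i], geno_effect[i], treat_geno) for i in range(n)]
        )
        mean_j = s[j] * mu * np.power(2.0, eff)
        counts[:, j] = nb_draws(rng, mean_j, config.dispersion)

    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=ids, columns=labels),
        samples=pd.DataFrame(
            {
                "genotype": [g for g, _t, _r in config.design],
                "treatment": [t for _g, t, _r in config.design],
                "replicate": [r for _g, _t, r in config.design],
            },
            index=labels,
        ),
    )
    matrix.validate()

    # contrast-level truth: B-over-A log2 fold changes of the planted effects
    contrast_defs = [
        ("HP_BR_vs_LP_BR", ("BR", "HP"), ("BR", "LP")),
        ("HP_NR_vs_LP_NR", ("NR", "HP"), ("NR", "LP")),
        ("HP_BR_vs_HP_NR", ("BR", "HP"), ("NR", "HP")),
        ("LP_BR_vs_LP_NR", ("BR", "LP"), ("NR", "LP")),
    ]
    cells = {(g, t) for g, t, _r in config.design}
    rows = []
    for name, (ga, ta), (gb, tb) in contrast_defs:
        if (ga, ta) not in cells or (gb, tb) not in cells:
            continue
        for i, tid in enumerate(ids):
            fc = _condition_effect(gb, tb, beta[i], geno_effect[i], treat_geno) - \
                _condition_effect(ga, ta, beta[i], geno_effect[i], treat_geno)
            if fc != 0.0:
                rows.append((tid, name, fc))
    truth.de = pd.DataFrame(rows, columns=["transcript", "contrast", "true_log2fc"])
    truth.size_factors = pd.Series(s, index=labels)
    return matrix


# ---------------------------------------------------------------------------
# miRNAs
# ---------------------------------------------------------------------------


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    arr = list(seq)
    for pos in rng.choice(len(seq), size=n_mut, replace=False):
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def _write_site(
    sequences: dict[str, np.ndarray],
    rec: TranscriptRecord,
    tx_pos: int,
    site: str,
) -> None:
    """Write ``site`` into the genome at transcript coordinates [tx_pos, ...).

    Only positions inside a single exon are supported (callers ensure this).
    """
    L = len(site)
    offsets = np.cumsum([0] + [e - s for s, e in rec.exons])
    if rec.strand == "-":
        # transcript coords run along the reverse complement
        tx_pos = rec.length - tx_pos - L
        site = revcomp(site)
    for k, (s, e) in enumerate(rec.exons):
        if offsets[k] <= tx_pos and tx_pos + L <= offsets[k + 1]:
            gstart = s + (tx_pos - offsets[k])
            sequences[rec.chrom][gstart:gstart + L] = np.frombuffer(
                site.encode(), dtype=np.uint8
            )
            return
    raise ValueError("site crosses an exon boundary")


def _single_exon_offset(rec: TranscriptRecord, tx_pos: int, L: int) -> bool:
    offsets = np.cumsum([0] + [e - s for s, e in rec.exons])
    pos = rec.length - tx_pos - L if rec.strand == "-" else tx_pos
    return any(
        offsets[k] <= pos and pos + L <= offsets[k + 1] for k in range(len(rec.exons))
    )


def generate_mirna_set(
    sequences: Mapping[str, str] | dict[str, str],
    transcripts: Sequence[TranscriptRecord],
    truth: TruthTable,
    config: SimulationConfig,
    cis_window: int = 10_000,
) -> tuple[dict[str, str], dict[str, str]]:
    """Mature miRNAs with planted precursors and planted target sites.

    Precursors are embedded (≤ the number of mismatches that keeps identity
    above 90 %) in intergenic/bidirectional lncRNAs; perfect complementary
    target sites go into the 3' tail of mRNAs that lie within ``cis_window``
    of a DE lncRNA, making them recoverable shared lncRNA/miRNA targets.
    Returns (miRNA sequences, updated chromosome sequences); transcript
    records touched by an embedding are re-extracted in place.
    """
    config.validate()
    rng = _rng(config, 3)
    mirnas: dict[str, str] = {}
    for i in range(config.n_mirnas):
        if i < len(P_RELATED_FAMILIES):
            mid = f"gma-{P_RELATED_FAMILIES[i]}"
        else:
            mid = f"gma-miR-syn{i + 1}"
        L = int(rng.choice([20, 21, 22, 23, 24], p=[0.15, 0.4, 0.2, 0.15, 0.1]))
        mirnas[mid] = _seq_str(_background(rng, L, 0.42))
    if not mirnas:
        return {}, dict(sequences)

    chrom_arrays = {
        c: np.frombuffer(s.encode(), dtype=np.uint8).copy() for c, s in sequences.items()
    }
    by_id = {t.id: t for t in transcripts}
    lnc_classes = truth.transcripts

    mirna_ids = sorted(mirnas)

    # --- precursors -------------------------------------------------------
    hosts = [
        t for t in transcripts
        if t.id in lnc_classes.index
        and not lnc_classes.loc[t.id, "true_coding"]
        and lnc_classes.loc[t.id, "true_class"] in ("intergenic", "bidirectional")
        and t.exon_count == 1
        and t.length >= 60
    ]
    rng.shuffle(hosts)
    prec_rows = []
    for k in range(config.n_planted_precursors):
        if k >= len(hosts):
            raise ValueError("hosts exhausted: not enough lncRNAs to carry precursors")
        host = hosts[k]
        mid = mirna_ids[k % len(mirna_ids)]
        mseq = mirnas[mid]
        L = len(mseq)
        max_mm = max(0, math.ceil(0.1 * L) - 1)
        n_mm = int(rng.integers(0, max_mm + 1))
        site = _mutate(rng, mseq, n_mm)
        if rng.random() < 0.5:
            site = revcomp(site)
        pos = int(rng.integers(5, host.length - L - 5))
        _write_site(chrom_arrays, host, pos, site)
        prec_rows.append((mid, host.id, (L - n_mm) / L))
    truth.mirna_precursors = pd.DataFrame(
        prec_rows, columns=["mirna_id", "lncrna_id", "identity"]
    )

    # --- planted shared targets ------------------------------------------
    de_lnc = [
        tid for tid in sorted(truth.de_ids())
        if tid in lnc_classes.index and not lnc_classes.loc[tid, "true_coding"]
    ]
    mrnas = [t for t in transcripts if lnc_classes.loc[t.id, "true_coding"]]
    lnc_spans = [
        by_id[i] for i in de_lnc if i in by_id
    ]
    lnc_intervals = [
        (t.id, t.chrom, t.start, t.end) for t in transcripts
        if not lnc_classes.loc[t.id, "true_coding"]
    ]

    def hosts_no_lnc_overlap(m: TranscriptRecord) -> bool:
        return not any(
            c == m.chrom and s < m.end and e > m.start
            for _i, c, s, e in lnc_intervals
        )

    candidates: list[tuple[str, TranscriptRecord]] = []  # (de lncRNA id, mRNA)
    seen = set()
    for m in mrnas:
        if not hosts_no_lnc_overlap(m):
            continue
        for lnc in lnc_spans:
            if lnc.chrom != m.chrom:
                continue
            if lnc.start < m.end and lnc.end > m.start:
                continue  # overlapping: not a cis pair
            gap = m.start - lnc.end if m.start >= lnc.end else lnc.start - m.end
            if 0 <= gap <= cis_window and m.id not in seen:
                candidates.append((lnc.id, m))
                seen.add(m.id)
                break
    rng.shuffle(candidates)
    tgt_rows, shared_rows = [], []
    placed = 0
    for lnc_id, m in candidates:
        if placed >= config.n_planted_mirna_targets:
            break
        mid = mirna_ids[placed % len(mirna_ids)]
        mseq = mirnas[mid]
        L = len(mseq)
        pos = None
        for k in range(12, 80):
            cand = m.length - L - k
            if cand <= 0:
                break
            if _single_exon_offset(m, cand, L):
                pos = cand
                break
        if pos is None:
            continue
        _write_site(chrom_arrays, m, pos, revcomp(mseq))
        gene_id = m.gene_id or m.id
        tgt_rows.append((mid, gene_id))
        shared_rows.append((gene_id, lnc_id, mid))
        placed += 1
    if placed < config.n_planted_mirna_targets:
        raise ValueError(
            "hosts exhausted: not enough mRNAs adjacent to DE lncRNAs for "
            f"planted miRNA targets (placed {placed})"
        )
    truth.mirna_targets = pd.DataFrame(tgt_rows, columns=["mirna_id", "gene_id"])
    truth.shared_targets = pd.DataFrame(
        shared_rows, columns=["gene_id", "lncrna_id", "mirna_id"]
    )

    new_sequences = {c: _seq_str(a) for c, a in chrom_arrays.items()}
    for t in transcripts:
        t.sequence = spliced_sequence(new_sequences, t)
    return mirnas, new_sequences


# ---------------------------------------------------------------------------
# qPCR panel
# ---------------------------------------------------------------------------

REFERENCE_GENE = "tubulin"
_REFERENCE_LEVEL = 4096.0  # constant normalized expression of the control


def generate_qpcr_panel(
    matrix: ExpressionMatrix,
    transcripts: Sequence[TranscriptRecord],
    truth: TruthTable,
    config: SimulationConfig,
    transcript_ids: Sequence[str] | None = None,
) -> CtPanel:
    """Ct panel: Ct = intercept − log2(normalized expression) + noise.

    Three technical replicates per well; the tubulin control sits at a
    constant normalized level in every sample.  The panel covers the HP/LP
    conditions of the genotype carrying the planted treatment effect.
    """
    config.validate()
    rng = _rng(config, 4)
    genotypes = sorted(set(matrix.samples["genotype"]))
    geno = "BR" if "BR" in genotypes else genotypes[0]
    sub = matrix.samples[matrix.samples["genotype"] == geno]
    labels = list(sub.index)
    norm = matrix.counts[labels].div(truth.size_factors[labels], axis=1)

    if transcript_ids is None:
        lnc = set(truth.lncrna_ids())
        de_first = [t for t in sorted(truth.de_ids("HP_BR_vs_LP_BR")) if t in lnc]
        pool = de_first + [t for t in sorted(lnc) if t not in de_first]
        positive = [t for t in pool if (norm.loc[t] > 0).all()]
        transcript_ids = positive[: config.qpcr_n_transcripts]
    else:
        transcript_ids = list(transcript_ids)
    for tid in transcript_ids:
        if norm.loc[tid].mean() <= 0:
            raise ValueError(f"transcript {tid} has zero normalized expression")

    rows = []
    for label in labels:
        cond = f"{sub.loc[label, 'treatment']}-{geno}"
        bio = int(sub.loc[label, "replicate"])
        for tid in transcript_ids:
            base = config.qpcr_intercept - math.log2(float(norm.loc[tid, label]))
            for tech in (1, 2, 3):
                rows.append(
                    (tid, cond, bio, tech, base + rng.normal(0, config.qpcr_sigma))
                )
        ref_base = config.qpcr_intercept - math.log2(_REFERENCE_LEVEL)
        for tech in (1, 2, 3):
            rows.append(
                (REFERENCE_GENE, cond, bio, tech, ref_base + rng.normal(0, config.qpcr_sigma))
            )
    data = pd.DataFrame(
        rows, columns=["transcript", "condition", "bio_rep", "tech_rep", "ct"]
    )
    return CtPanel(data=data, reference=REFERENCE_GENE, calibrator=f"HP-{geno}")


# ---------------------------------------------------------------------------
# annotation map + interest labels (inputs for enrich / network stages)
# ---------------------------------------------------------------------------

_TERM_POOL = (
    [("GO:SYN%04d" % i, name, "BP") for i, name in enumerate(
        ["metabolic process", "lipid metabolic process", "signal transduction",
         "phosphate ion transport", "nitrogen fixation", "response to stress",
         "cellular process", "root development", "transcription regulation",
         "carbohydrate metabolic process", "hormone signaling", "ion homeostasis"], 1)]
    + [("GO:SYN%04d" % i, name, "MF") for i, name in enumerate(
        ["catalytic activity", "binding", "phosphatase activity",
         "transporter activity", "kinase activity", "DNA binding",
         "oxidoreductase activity"], 101)]
    + [("GO:SYN%04d" % i, name, "CC") for i, name in enumerate(
        ["membrane", "cell part", "organelle", "nucleus", "cytoplasm"], 201)]
    + [("KEGG:SYN%04d" % i, name, "KEGG") for i, name in enumerate(
        ["glycolysis", "starch and sucrose metabolism", "fatty acid biosynthesis",
         "plant hormone signal transduction", "phenylpropanoid biosynthesis",
         "pentose phosphate pathway", "circadian rhythm", "nitrogen metabolism"], 301)]
)


def generate_annotation_map(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> pd.DataFrame:
    """Generic GO/KEGG-style gene→term map over the coding genes."""
    rng = _rng(config, 5)
    # common terms get higher weight so enrichment has structure
    weights = np.array([2.0 if i % 3 == 0 else 1.0 for i in range(len(_TERM_POOL))])
    weights /= weights.sum()
    rows = []
    for gid in sorted(annotation.coding_genes()):
        k = min(len(_TERM_POOL), 1 + int(rng.poisson(1.8)))
        for idx in rng.choice(len(_TERM_POOL), size=k, replace=False, p=weights):
            term_id, name, cat = _TERM_POOL[idx]
            rows.append((gid, term_id, name, cat))
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name", "category"])


def generate_interest_labels(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> dict[str, str]:
    """TF / P_related / hormone labels for a subset of coding genes."""
    rng = _rng(config, 6)
    labels: dict[str, str] = {}
    for gid in sorted(annotation.coding_genes()):
        u = rng.random()
        if u < 0.08:
            labels[gid] = "TF"
        elif u < 0.13:
            labels[gid] = "P_related"
        elif u < 0.17:
            labels[gid] = "hormone"
    return labels
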