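"""cis / antisense / trans target prediction for DE lncRNAs.

cis: coding genes whose span lies within a 10-kb window (inclusive) on either
side of the lncRNA, overlap excluded.  antisense: local duplex alignment of
the lncRNA against the reverse complement of its overlapped gene's mRNA,
with G:U wobble credit.  trans: Pearson correlation of log2(FPKM+1) profiles
across all samples, with BH-corrected correlation-test p-values.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_io import GenomeAnnotation, TranscriptRecord, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetPair:
    lncrna_id: str
    gene_id: str
    mode: str  # "cis" | "antisense" | "trans"
    score: float  # distance bp (cis), normalized duplex score (antisense), r (trans)


# ---------------------------------------------------------------------------
# cis
# ---------------------------------------------------------------------------


def cis_targets(
    record: TranscriptRecord,
    annotation: GenomeAnnotation,
    window: int = 10_000,
) -> list[TargetPair]:
    """Non-overlapping coding genes within ``window`` bp of the lncRNA span.

    The boundary is inclusive: a gap of exactly ``window`` is reported.
    Score is the gap in bp (0 means adjacent, not overlapping).
    """
    pairs = []
    for g in annotation.coding_genes().values():
        if g.chrom != record.chrom:
            continue
        if g.start < record.end and g.end > record.start:
            continue  # overlap: handled by the antisense/sense machinery
        gap = g.start - record.end if g.start >= record.end else record.start - g.end
        if 0 <= gap <= window:
            pairs.append(TargetPair(record.id, g.id, "cis", float(gap)))
    pairs.sort(key=lambda p: (p.score, p.gene_id))
    return pairs


def cis_targets_all(
    records: Sequence[TranscriptRecord],
    annotation: GenomeAnnotation,
    window: int = 10_000,
) -> list[TargetPair]:
    """Window search over many lncRNAs using a sorted per-chromosome index."""
    genes_by_chrom: dict[str, list] = {}
    for g in annotation.coding_genes().values():
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    starts: dict[str, list[int]] = {}
    max_len: dict[str, int] = {}
    for chrom, genes in genes_by_chrom.items():
        genes.sort(key=lambda g: (g.start, g.id))
        starts[chrom] = [g.start for g in genes]
        max_len[chrom] = max(g.end - g.start for g in genes)
    out: list[TargetPair] = []
    for rec in records:
        genes = genes_by_chrom.get(rec.chrom)
        if not genes:
            continue
        lo = bisect_left(starts[rec.chrom], rec.start - window - max_len[rec.chrom])
        hi = bisect_right(starts[rec.chrom], rec.end + window)
        for g in genes[lo:hi]:
            if g.start < rec.end and g.end > rec.start:
                continue
            gap = g.start - rec.end if g.start >= rec.end else rec.start - g.end
            if 0 <= gap <= window:
                out.append(TargetPair(rec.id, g.id, "cis", float(gap)))
    out.sort(key=lambda p: (p.lncrna_id, p.score, p.gene_id))
    return out


# ---------------------------------------------------------------------------
# antisense
# ---------------------------------------------------------------------------


def _duplex_aligner() -> Align.PairwiseAligner:
    """Local aligner: match +1, G:U wobble +0.5, mismatch −1, gap −2.

    The lncRNA is aligned against the reverse complement of the mRNA, so a
    character match means a Watson–Crick pair and the wobble pairs G:U / U:G
    appear as (G,A) and (T,C) in alignment space.
    """
    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            if "N" in (x, y):
                m[x, y] = -1.0
            elif x == y:
                m[x, y] = 1.0
            elif (x, y) in (("G", "A"), ("T", "C")):
                m[x, y] = 0.5
            else:
                m[x, y] = -1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = m
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


_ALIGNER: Align.PairwiseAligner | None = None


def antisense_duplex_score(lncrna_seq: str, mrna_seq: str) -> tuple[float, int]:
    """Best local duplex score of the lncRNA vs the mRNA, normalized by the
    number of lncRNA bases in the alignment.  Returns (score, aligned_len)."""
    if len(lncrna_seq) < 20 or len(mrna_seq) < 20:
        raise ValueError("both sequences must be at least 20 nt")
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = _duplex_aligner()
    target = revcomp(mrna_seq.upper())
    alignment = _ALIGNER.align(lncrna_seq.upper(), target)[0]
    aligned_len = int(sum(e - s for s, e in alignment.aligned[0]))
    if aligned_len == 0:
        return 0.0, 0
    return float(alignment.score) / aligned_len, aligned_len


def antisense_pairs(
    lnc_records: Mapping[str, TranscriptRecord],
    mrna_seqs: Mapping[str, str],
    overlapped_gene: Mapping[str, str],
    score_threshold: float = 0.8,
    min_aligned: int = 50,
) -> list[TargetPair]:
    """Duplex scoring of antisense-class lncRNAs against their overlapped
    gene's mRNA; a pair is kept iff score ≥ threshold over ≥ min_aligned nt."""
    out = []
    for lnc_id, gene_id in sorted(overlapped_gene.items()):
        rec = lnc_records.get(lnc_id)
        seq = mrna_seqs.get(gene_id)
        if rec is None or seq is None:
            continue
        score, aligned = antisense_duplex_score(rec.sequence, seq)
        if score >= score_threshold and aligned >= min_aligned:
            out.append(TargetPair(lnc_id, gene_id, "antisense", round(score, 6)))
    return out


# ---------------------------------------------------------------------------
# trans
# ---------------------------------------------------------------------------


def trans_targets(
    fpkm: pd.DataFrame,
    lncrna_ids: Sequence[str],
    mrna_ids: Sequence[str],
    r_threshold: float = 0.95,
    fdr_threshold: float = 0.05,
    exclude: Iterable[tuple[str, str]] = (),
) -> list[TargetPair]:
    """Expression-correlation (trans) targets on the log2(FPKM+1) scale.

    Pearson r across all samples for every lncRNA × mRNA pair; a pair is
    reported iff |r| ≥ r_threshold and the BH-adjusted correlation-test p is
    < fdr_threshold.  Pairs in ``exclude`` (e.g. cis pairs) are dropped;
    zero-variance profiles are skipped with a log message.
    """
    n = fpkm.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples for trans correlation")
    X = np.log2(fpkm + 1.0)
    lnc = X.reindex(list(lncrna_ids)).to_numpy()
    mrna = X.reindex(list(mrna_ids)).to_numpy()

    def standardize(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu = mat.mean(axis=1, keepdims=True)
        sd = mat.std(axis=1, ddof=0, keepdims=True)
        ok = sd[:, 0] > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (mat - mu) / sd
        return z, ok

    zl, okl = standardize(lnc)
    zm, okm = standardize(mrna)
    for ids, ok in ((lncrna_ids, okl), (mrna_ids, okm)):
        for i, flag in enumerate(ok):
            if not flag:
                logger.info("trans_targets: zero-variance profile %s skipped", ids[i])
    r = (zl @ zm.T) / n
    r = np.clip(r, -1.0, 1.0)

    excluded = set(exclude)
    rows, cols, rvals = [], [], []
    for i, lid in enumerate(lncrna_ids):
        if not okl[i]:
            continue
        for j, mid in enumerate(mrna_ids):
            if not okm[j] or lid == mid or (lid, mid) in excluded:
                continue
            rows.append(lid)
            cols.append(mid)
            rvals.append(r[i, j])
    if not rows:
        return []
    rv = np.array(rvals)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((n - 2) / np.clip(1 - rv**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    q = multipletests(p, method="fdr_bh")[1]
    keep = (np.abs(rv) >= r_threshold) & (q < fdr_threshold)
    pairs = [
        TargetPair(rows[k], cols[k], "trans", float(round(rv[k], 6)))
        for k in np.flatnonzero(keep)
    ]
    pairs.sort(key=lambda pair: (pair.lncrna_id, pair.gene_id))
    return pairs


def pairs_frame(pairs: Iterable[TargetPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.lncrna_id, p.gene_id, p.mode, p.score) for p in pairs],
        columns=["lncrna_id", "gene_id", "mode", "score"],
    )
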