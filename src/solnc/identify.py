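"""lncRNA candidate selection: length/exon filters plus a two-scorer
coding-potential intersection rule.

A transcript is kept as a lncRNA only if BOTH an ORF-feature scorer and a
hexamer (dicodon) log-likelihood-ratio scorer call it noncoding.  The two
scorers are deliberately independent in what they look at: the first uses
open-reading-frame geometry, the second codon-usage composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genomic_io import TranscriptRecord

# ---------------------------------------------------------------------------
# Fixed composition models
# ---------------------------------------------------------------------------

#: Relative codon usage (per-thousand scale, dicot-flavoured). Stop codons get
#: a small positive mass so the derived hexamer table is strictly positive.
#: The synthetic-data generator draws CDS codons from this same table, which
#: makes the intersection rule testable end to end.
CODON_FREQUENCIES: dict[str, float] = {
    "TTT": 21.8, "TTC": 17.9, "TTA": 12.2, "TTG": 21.5,
    "CTT": 24.1, "CTC": 16.0, "CTA": 9.9, "CTG": 9.7,
    "ATT": 21.5, "ATC": 14.8, "ATA": 12.5, "ATG": 24.5,
    "GTT": 27.1, "GTC": 12.7, "GTA": 9.9, "GTG": 17.4,
    "TCT": 25.2, "TCC": 11.1, "TCA": 18.3, "TCG": 9.3,
    "CCT": 18.8, "CCC": 5.3, "CCA": 16.1, "CCG": 8.4,
    "ACT": 17.5, "ACC": 10.3, "ACA": 15.7, "ACG": 7.6,
    "GCT": 28.2, "GCC": 10.2, "GCA": 17.5, "GCG": 8.6,
    "TAT": 14.6, "TAC": 13.7, "TAA": 1.0, "TAG": 0.5,
    "CAT": 13.8, "CAC": 8.7, "CAA": 19.4, "CAG": 15.2,
    "AAT": 22.3, "AAC": 20.9, "AAA": 30.5, "AAG": 32.8,
    "GAT": 36.6, "GAC": 17.2, "GAA": 34.3, "GAG": 32.2,
    "TGT": 10.5, "TGC": 7.2, "TGA": 1.2, "TGG": 12.4,
    "CGT": 9.0, "CGC": 3.8, "CGA": 6.3, "CGG": 4.9,
    "AGT": 13.9, "AGC": 11.3, "AGA": 19.0, "AGG": 11.0,
    "GGT": 22.3, "GGC": 12.2, "GGA": 24.2, "GGG": 10.2,
}

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def codon_probabilities(include_stops: bool = True) -> dict[str, float]:
    """Normalized codon distribution from :data:`CODON_FREQUENCIES`."""
    items = {
        c: f for c, f in CODON_FREQUENCIES.items() if include_stops or c not in STOP_CODONS
    }
    total = sum(items.values())
    return {c: f / total for c, f in items.items()}


def default_coding_hexamer_table() -> np.ndarray:
    """4096-entry coding hexamer (dicodon) distribution, strictly positive.

    Hexamer probability is the product of the two in-frame codon
    probabilities (codon-independence model), normalized.
    """
    p = codon_probabilities(include_stops=True)
    table = np.zeros(4096)
    codons = sorted(p)
    for c1 in codons:
        i1 = _codon_index(c1)
        for c2 in codons:
            table[i1 * 64 + _codon_index(c2)] = p[c1] * p[c2]
    return table / table.sum()


def default_noncoding_hexamer_table(gc: float = 0.35) -> np.ndarray:
    """Background hexamer distribution: i.i.d. nucleotides at the given GC."""
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    pnt = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    table = np.ones(4096)
    for pos in range(6):
        idx = (np.arange(4096) // 4 ** (5 - pos)) % 4
        table *= pnt[idx]
    return table / table.sum()


def _codon_index(codon: str) -> int:
    return (_BASE_INDEX[codon[0]] * 4 + _BASE_INDEX[codon[1]]) * 4 + _BASE_INDEX[codon[2]]


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T → 0..3; anything else (N) → -1."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, code in _BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


# ---------------------------------------------------------------------------
# Results container
# ---------------------------------------------------------------------------


@dataclass
class CodingPotentialResult:
    transcript_id: str
    longest_orf_nt: int
    orf_coverage: float
    hexamer_llr: float
    call_orf: str  # "coding" | "noncoding"
    call_hexamer: str
    final: str  # "lncRNA" | "rejected"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def filter_candidates(
    transcripts: Iterable[TranscriptRecord],
    min_length: int = 200,
    min_exons: int = 1,
    known_mrna_ids: set[str] | frozenset[str] = frozenset(),
) -> list[TranscriptRecord]:
    """Length/exon pre-filter for lncRNA candidacy.

    Keeps transcripts strictly longer than ``min_length`` with at least
    ``min_exons`` exons, excluding annotated mRNAs of coding genes.
    """
    kept = []
    for t in transcripts:
        if t.id in known_mrna_ids:
            continue
        if t.length > min_length and t.exon_count >= min_exons:
            kept.append(t)
    return kept


def orf_coding_score(
    sequence: str, orf_min_len: int = 300, orf_min_coverage: float = 0.5
) -> tuple[int, float, str]:
    """Longest ATG…stop ORF over the 3 forward frames and the resulting call.

    The ORF length counts start and stop codons.  Codons containing N break an
    ORF.  Call is "coding" iff the longest ORF is at least ``orf_min_len`` nt
    or covers at least ``orf_min_coverage`` of the transcript.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    n = len(seq)
    best = 0
    enc = _encode(seq)
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon_enc = enc[pos:pos + 3]
            if (codon_enc < 0).any():
                start = None  # N breaks the frame
                continue
            codon = seq[pos:pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS:
                best = max(best, pos + 3 - start)
                start = None
    coverage = best / n
    call = "coding" if (best >= orf_min_len or coverage >= orf_min_coverage) else "noncoding"
    return best, coverage, call


def hexamer_llr(
    sequence: str,
    coding_table: np.ndarray | Mapping[str, float] | None = None,
    noncoding_table: np.ndarray | Mapping[str, float] | None = None,
) -> tuple[float, str]:
    """Best-frame sum of log(p_coding/p_noncoding) over in-frame hexamers.

    Hexamers are read in steps of 3 (successive dicodons); the maximum over
    the 3 forward frames is returned.  Hexamers containing N are skipped.
    Call is "coding" iff llr > 0.
    """
    if len(sequence) < 6:
        raise ValueError("sequence shorter than 6 nt")
    ct = _as_table(coding_table, default_coding_hexamer_table)
    nt = _as_table(noncoding_table, lambda: default_noncoding_hexamer_table())
    if (ct <= 0).any() or (nt <= 0).any():
        raise ValueError("hexamer tables must be strictly positive")
    logratio = np.log(ct) - np.log(nt)
    enc = _encode(sequence.upper())
    n = len(enc)
    powers = 4 ** np.arange(5, -1, -1)
    best = -math.inf
    for frame in range(3):
        positions = np.arange(frame, n - 5, 3)
        if positions.size == 0:
            continue
        windows = enc[positions[:, None] + np.arange(6)]
        valid = (windows >= 0).all(axis=1)
        if not valid.any():
            score = 0.0
        else:
            idx = windows[valid] @ powers
            score = float(logratio[idx].sum())
        best = max(best, score)
    if best == -math.inf:
        best = 0.0
    call = "coding" if best > 0 else "noncoding"
    return best, call


def _as_table(table, default_factory) -> np.ndarray:
    if table is None:
        return default_factory()
    if isinstance(table, np.ndarray):
        arr = table.astype(float)
    else:
        arr = np.zeros(4096)
        for hexamer, p in table.items():
            idx = 0
            for base in hexamer:
                idx = idx * 4 + _BASE_INDEX[base]
            arr[idx] = p
    s = arr.sum()
    if s <= 0:
        raise ValueError("hexamer table has no mass")
    return arr / s


def score_transcripts(
    candidates: Sequence[TranscriptRecord],
    coding_table: np.ndarray | None = None,
    noncoding_table: np.ndarray | None = None,
    orf_min_len: int = 300,
    orf_min_coverage: float = 0.5,
) -> list[CodingPotentialResult]:
    """Run both coding-potential scorers on every candidate."""
    results = []
    for t in candidates:
        orf_nt, cov, call_orf = orf_coding_score(t.sequence, orf_min_len, orf_min_coverage)
        llr, call_hex = hexamer_llr(t.sequence, coding_table, noncoding_table)
        final = "lncRNA" if (call_orf == "noncoding" and call_hex == "noncoding") else "rejected"
        results.append(
            CodingPotentialResult(
                transcript_id=t.id,
                longest_orf_nt=orf_nt,
                orf_coverage=cov,
                hexamer_llr=llr,
                call_orf=call_orf,
                call_hexamer=call_hex,
                final=final,
            )
        )
    return results


def call_lncrnas(
    candidates: Sequence[TranscriptRecord],
    results: Sequence[CodingPotentialResult],
) -> list[TranscriptRecord]:
    """Intersection rule: lncRNA iff both scorers called noncoding."""
    by_id = {r.transcript_id: r for r in results}
    out = []
    for t in candidates:
        r = by_id.get(t.id)
        if r is None:
            raise ValueError(f"no coding-potential result for candidate {t.id}")
        if r.final == "lncRNA":
            out.append(t)
    return out
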