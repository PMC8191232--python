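"""miRNA precursor detection and plant-rule target scoring.

Precursors: a lncRNA hosts a candidate precursor if the mature miRNA (or its
reverse complement) matches it ungapped at more than ``min_identity`` over
the full miRNA length.  Targets: every ungapped placement of the miRNA on the
transcript's complement is scored by the plant penalty scheme — mismatch 1.0,
G:U wobble 0.5, doubled inside the 5' core (miRNA positions 2–13) — and a
site is reported when the penalty is at most the cutoff (default 4.0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genomic_io import revcomp
from .targets import TargetPair

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)  # 4 == N / unknown
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


@dataclass(frozen=True)
class MirnaHit:
    mirna_id: str
    transcript_id: str
    kind: str  # "precursor_similarity" | "target_site"
    start: int  # site coordinates on the subject transcript, half-open
    end: int
    identity: float | None = None
    penalty: float | None = None
    strand: str = "+"


# ---------------------------------------------------------------------------
# precursor similarity
# ---------------------------------------------------------------------------


def _best_ungapped(mirna: np.ndarray, subject: np.ndarray) -> tuple[int, int]:
    """(best match count, offset) of a full-length ungapped placement."""
    L = len(mirna)
    if len(subject) < L:
        return 0, -1
    windows = np.lib.stride_tricks.sliding_window_view(subject, L)
    matches = (windows == mirna).sum(axis=1)
    off = int(matches.argmax())
    return int(matches[off]), off


def precursor_similarity(
    mirna_id: str,
    mirna_seq: str,
    lncrna_id: str,
    lncrna_seq: str,
    min_identity: float = 0.9,
) -> MirnaHit | None:
    """Best ungapped local match of the miRNA or its reverse complement.

    identity = matches / miRNA length; a hit needs identity strictly greater
    than ``min_identity`` ("more than 90 % similarity").
    """
    if not 18 <= len(mirna_seq) <= 26:
        raise ValueError(f"mature miRNA {mirna_id} must be 18-26 nt")
    m_fwd = _encode(mirna_seq)
    m_rev = _encode(revcomp(mirna_seq.upper()))
    subject = _encode(lncrna_seq)
    best_fwd, off_fwd = _best_ungapped(m_fwd, subject)
    best_rev, off_rev = _best_ungapped(m_rev, subject)
    if best_fwd >= best_rev:
        best, off, strand = best_fwd, off_fwd, "+"
    else:
        best, off, strand = best_rev, off_rev, "-"
    if off < 0:
        return None
    identity = best / len(mirna_seq)
    if identity > min_identity:
        return MirnaHit(
            mirna_id=mirna_id,
            transcript_id=lncrna_id,
            kind="precursor_similarity",
            start=off,
            end=off + len(mirna_seq),
            identity=identity,
            strand=strand,
        )
    return None


# ---------------------------------------------------------------------------
# target scoring
# ---------------------------------------------------------------------------


def target_penalties(mirna_seq: str, transcript_seq: str) -> np.ndarray:
    """Penalty of every ungapped placement of the miRNA on the transcript.

    Placement at offset o pairs the miRNA (5'→3') antiparallel with
    transcript[o:o+L]; per position the pair contributes 0 (Watson–Crick),
    0.5 (G:U wobble) or 1.0 (mismatch; N counts as mismatch), doubled at
    miRNA positions 2–13.
    """
    m = _encode(mirna_seq)
    L = len(m)
    subject = _encode(transcript_seq)
    if len(subject) < L:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(subject, L)
    # reverse-complement each window so that column k faces miRNA position k
    wrc = windows[:, ::-1]
    comp = np.where(wrc <= 3, 3 - wrc, 4)
    match = comp == m
    gu = ((m == _BASE_CODE["G"]) & (comp == _BASE_CODE["A"])) | (
        (m == _BASE_CODE["T"]) & (comp == _BASE_CODE["C"])
    )
    per_pos = np.where(match, 0.0, np.where(gu, 0.5, 1.0))
    weights = np.ones(L)
    weights[1:13] = 2.0  # miRNA positions 2-13, 5'->3'
    return per_pos @ weights


def mirna_target_sites(
    mirna_id: str,
    mirna_seq: str,
    transcript_id: str,
    transcript_seq: str,
    cutoff: float = 4.0,
) -> list[MirnaHit]:
    """All target sites with penalty ≤ cutoff, with subject coordinates."""
    if len(transcript_seq) < len(mirna_seq):
        return []
    penalties = target_penalties(mirna_seq, transcript_seq)
    L = len(mirna_seq)
    hits = []
    for off in np.flatnonzero(penalties <= cutoff):
        hits.append(
            MirnaHit(
                mirna_id=mirna_id,
                transcript_id=transcript_id,
                kind="target_site",
                start=int(off),
                end=int(off) + L,
                penalty=float(penalties[off]),
            )
        )
    return hits


def scan_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    cutoff: float = 4.0,
) -> list[MirnaHit]:
    hits: list[MirnaHit] = []
    for mid in sorted(mirnas):
        for tid in sorted(transcripts):
            hits.extend(mirna_target_sites(mid, mirnas[mid], tid, transcripts[tid], cutoff))
    return hits


def scan_precursors(
    mirnas: Mapping[str, str],
    lncrnas: Mapping[str, str],
    min_identity: float = 0.9,
) -> list[MirnaHit]:
    hits: list[MirnaHit] = []
    for mid in sorted(mirnas):
        for lid in sorted(lncrnas):
            hit = precursor_similarity(mid, mirnas[mid], lid, lncrnas[lid], min_identity)
            if hit is not None:
                hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# shared targets
# ---------------------------------------------------------------------------


def is_family_member(mirna_id: str, families: Iterable[str]) -> bool:
    return any(fam in mirna_id for fam in families)


def shared_target_intersection(
    lncrna_pairs: Sequence[TargetPair],
    mirna_hits: Sequence[MirnaHit],
    p_related_mirnas: Sequence[str],
) -> dict[str, tuple[set[str], set[str]]]:
    """mRNAs targeted both by ≥1 listed-family miRNA and ≥1 DE lncRNA.

    Returns {mRNA id: (contributing lncRNA ids, contributing miRNA ids)}.
    """
    by_mrna_lnc: dict[str, set[str]] = {}
    for p in lncrna_pairs:
        by_mrna_lnc.setdefault(p.gene_id, set()).add(p.lncrna_id)
    by_mrna_mir: dict[str, set[str]] = {}
    for h in mirna_hits:
        if h.kind != "target_site":
            continue
        if not is_family_member(h.mirna_id, p_related_mirnas):
            continue
        by_mrna_mir.setdefault(h.transcript_id, set()).add(h.mirna_id)
    shared = {}
    for mrna in sorted(set(by_mrna_lnc) & set(by_mrna_mir)):
        shared[mrna] = (by_mrna_lnc[mrna], by_mrna_mir[mrna])
    return shared
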