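import numpy as np
import pandas as pd
import pytest

from solnc import targets
from solnc.genomic_io import Gene, GenomeAnnotation, Transcript, TranscriptRecord, revcomp


def _ann(gene_spans):
    genes, transcripts = {}, {}
    for gid, (chrom, start, end, strand) in gene_spans.items():
        genes[gid] = Gene(id=gid, chrom=chrom, strand=strand, start=start, end=end)
        transcripts[f"{gid}.1"] = Transcript(
            id=f"{gid}.1", gene_id=gid, chrom=chrom, strand=strand,
            exons=((start, end),),
        )
    return GenomeAnnotation(genes=genes, transcripts=transcripts)


def _lnc(start, end, chrom="c1", strand="+", tid="lnc1"):
    return TranscriptRecord(
        id=tid, chrom=chrom, strand=strand, exons=((start, end),),
        sequence="A" * (end - start),
    )


class TestCis:
    def test_gap_window_boundary_inclusive(self):
        ann = _ann({
            "near": ("c1", 0, 5000, "+"),        # gap to lncRNA = 10_000
            "far": ("c1", 40_001, 42_000, "+"),  # gap = 10_001
        })
        rec = _lnc(15_000, 30_000)
        pairs = targets.cis_targets(rec, ann, window=10_000)
        assert [p.gene_id for p in pairs] == ["near"]
        assert pairs[0].score == 10_000

    def test_gene_just_inside_window_upstream(self):
        ann = _ann({"g": ("c1", 0, 5001, "+")})  # ends 9_999 before lncRNA
        pairs = targets.cis_targets(_lnc(15_000, 16_000), ann, window=10_000)
        assert len(pairs) == 1

    def test_overlapping_gene_excluded(self):
        ann = _ann({"g": ("c1", 900, 1200, "+")})
        assert targets.cis_targets(_lnc(1000, 2000), ann) == []

    def test_reflection_symmetry(self, rng):
        """Mirroring all coordinates preserves the cis pair set."""
        L = 100_000
        ann = _ann({
            "g1": ("c1", 5000, 8000, "+"),
            "g2": ("c1", 30_000, 33_000, "-"),
        })
        rec = _lnc(12_000, 14_000)
        mirrored = _ann({
            "g1": ("c1", L - 8000, L - 5000, "-"),
            "g2": ("c1", L - 33_000, L - 30_000, "+"),
        })
        rec_m = _lnc(L - 14_000, L - 12_000, strand="-")
        p1 = {(p.gene_id, p.score) for p in targets.cis_targets(rec, ann)}
        p2 = {(p.gene_id, p.score) for p in targets.cis_targets(rec_m, mirrored)}
        assert p1 == p2

    def test_indexed_equals_bruteforce_on_random_layouts(self, rng):
        for _ in range(200):
            n_genes = int(rng.integers(2, 12))
            spans = {}
            pos = 0
            for i in range(n_genes):
                pos += int(rng.integers(0, 15_000))
                length = int(rng.integers(500, 4000))
                spans[f"g{i}"] = ("c1", pos, pos + length,
                                  "+" if rng.random() < 0.5 else "-")
                pos += length
            ann = _ann(spans)
            recs = []
            for k in range(3):
                s = int(rng.integers(0, pos + 12_000))
                recs.append(_lnc(s, s + int(rng.integers(200, 3000)), tid=f"l{k}"))
            indexed = {
                (p.lncrna_id, p.gene_id, p.score)
                for p in targets.cis_targets_all(recs, ann, window=10_000)
            }
            brute = set()
            for rec in recs:
                for gid, (_c, gs, ge, _s) in spans.items():
                    if gs < rec.end and ge > rec.start:
                        continue
                    gap = gs - rec.end if gs >= rec.end else rec.start - ge
                    if 0 <= gap <= 10_000:
                        brute.add((rec.id, gid, float(gap)))
            assert indexed == brute


class TestAntisenseDuplex:
    def test_perfect_reverse_complement_scores_one(self, rng):
        lnc = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 120)])
        score, aligned = targets.antisense_duplex_score(lnc, revcomp(lnc))
        assert score == pytest.approx(1.0)
        assert aligned == 120

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="20 nt"):
            targets.antisense_duplex_score("ACGT", "ACGTACGTACGTACGTACGTACGT")

    def test_scattered_mismatches_deterministic(self, rng):
        lnc = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        mrna = list(revcomp(lnc))
        for pos in range(0, 200, 10):  # 10 % mismatches
            mrna[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mrna[pos]]
        mrna = "".join(mrna)
        s1, _ = targets.antisense_duplex_score(lnc, mrna)
        s2, _ = targets.antisense_duplex_score(lnc, mrna)
        assert s1 == s2
        assert 0.5 < s1 < 1.0

    def test_null_random_pairs_stay_below_threshold(self):
        rng = np.random.default_rng(77)
        bases = np.array(list("ACGT"))
        p = [0.325, 0.175, 0.175, 0.325]  # GC 0.35
        below = 0
        n = 1000
        for _ in range(n):
            a = "".join(bases[rng.choice(4, 500, p=p)])
            b = "".join(bases[rng.choice(4, 500, p=p)])
            score, _ = targets.antisense_duplex_score(a, b)
            below += score < 0.8
        assert below / n >= 0.99


class TestTrans:
    def _fpkm(self, rows):
        frame = pd.DataFrame(rows).T
        frame.columns = [f"s{i}" for i in range(frame.shape[1])]
        return frame

    def test_identical_profiles_give_r_one(self, rng):
        x = rng.random(12) * 100
        fpkm = self._fpkm({"l1": x, "m1": x})
        pairs = targets.trans_targets(fpkm, ["l1"], ["m1"])
        assert len(pairs) == 1
        assert pairs[0].score == pytest.approx(1.0)

    def test_anticorrelated_profile_reported_negative(self, rng):
        x = np.linspace(1, 50, 12)
        y = 2 ** (-np.log2(x + 1)) - 1  # log2(y+1) = -log2(x+1)
        fpkm = pd.DataFrame({"l1": x, "m1": y}).T
        fpkm.columns = [f"s{i}" for i in range(12)]
        pairs = targets.trans_targets(fpkm, ["l1"], ["m1"], r_threshold=0.95)
        assert len(pairs) == 1
        assert pairs[0].score == pytest.approx(-1.0, abs=1e-9)

    def test_affine_transform_invariance(self, rng):
        x = rng.random(12) * 50
        y = rng.random(12) * 50
        f1 = pd.DataFrame({"l1": x, "m1": y}).T
        f1.columns = [f"s{i}" for i in range(12)]
        r1 = np.corrcoef(np.log2(x + 1), np.log2(y + 1))[0, 1]
        # affine transform on the log scale preserves Pearson r
        z1 = 3 * np.log2(x + 1) + 2
        r2 = np.corrcoef(z1, np.log2(y + 1))[0, 1]
        assert r1 == pytest.approx(r2)

    def test_null_profiles_rarely_reported(self, rng):
        n_l, n_m = 100, 60
        counts = rng.negative_binomial(20, 20 / (20 + 100), size=(n_l + n_m, 12))
        fpkm = pd.DataFrame(
            counts.astype(float), columns=[f"s{i}" for i in range(12)],
            index=[f"l{i}" for i in range(n_l)] + [f"m{i}" for i in range(n_m)],
        )
        pairs = targets.trans_targets(
            fpkm, [f"l{i}" for i in range(n_l)], [f"m{i}" for i in range(n_m)],
            r_threshold=0.95,
        )
        assert len(pairs) / (n_l * n_m) <= 0.001

    def test_zero_variance_profile_skipped_not_fatal(self, rng):
        fpkm = pd.DataFrame(
            {"l1": np.ones(12), "m1": rng.random(12)}
        ).T
        fpkm.columns = [f"s{i}" for i in range(12)]
        assert targets.trans_targets(fpkm, ["l1"], ["m1"]) == []

    def test_too_few_samples_rejected(self):
        fpkm = pd.DataFrame({"l1": [1, 2, 3], "m1": [1, 2, 3]}).T
        fpkm.columns = ["a", "b", "c"]
        with pytest.raises(ValueError, match="4 samples"):
            targets.trans_targets(fpkm, ["l1"], ["m1"])

    def test_cis_pairs_excluded(self, rng):
        x = rng.random(12) * 100
        fpkm = pd.DataFrame({"l1": x, "m1": x}).T
        fpkm.columns = [f"s{i}" for i in range(12)]
        pairs = targets.trans_targets(fpkm, ["l1"], ["m1"], exclude={("l1", "m1")})
        assert pairs == []
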