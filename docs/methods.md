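# Methods

This note documents the models, the parameter choices and the numerical
conventions behind `solnc`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and formats

All in-memory coordinates are 0-based half-open; GTF files are 1-based
inclusive on disk and converted only at the GTF boundary, so there is a
single place where an off-by-one could exist, and the conversion is tested
as an involution. Strand "." is rejected at parse time: positional
classification and divergent-promoter detection are undefined without
orientation. FASTA is case-normalized to uppercase on read. All writers emit
a `# solnc <version> seed=<seed>` header comment and no timestamps, which is
what makes reruns byte-identical.

## Coding-potential filtering (identify)

A transcript is a lncRNA candidate if it is longer than 200 nt (strict) and
it is not an annotated mRNA. The exon-count rule is configurable with
`min_exons = 1` by default: single-exon lncRNAs dominate real plant data
sets, so a "multi-exon only" reading would discard most of the class; the
stricter reading remains available via configuration.

Two independent scorers must both call "noncoding" for a candidate to
survive (intersection rule):

* **ORF features** — the longest ATG…stop open reading frame over the three
  forward frames (reverse frames are not scanned: assembled transcripts are
  oriented). The ORF length counts start and stop codons; codons containing
  N break the frame. Coding iff longest ORF ≥ 300 nt or ORF coverage ≥ 0.5.
  These are conventional lncRNA-calling values — 300 nt ≈ 100 aa, the usual
  boundary below which random ORFs are common.
* **Hexamer usage** — the best-frame sum of log(p_coding/p_noncoding) over
  successive in-frame hexamers (dicodons, step 3). Coding iff LLR > 0.
  Hexamers containing N are skipped. The coding table is the outer product
  of a fixed dicot-style codon-usage table (stop codons carry a small
  positive mass so the table is strictly positive); the noncoding table is
  an i.i.d. nucleotide model at GC 0.35. The synthetic generator samples
  CDS codons from the same codon table, which makes the intersection rule a
  closed, testable loop: on default synthetic data ≥ 95 % of true lncRNAs
  survive and ≥ 95 % of mRNAs are rejected (measured ≈ 98 % and 100 %).

Shortening a transcript's longest ORF can never flip a call from noncoding
to coding (both criteria are monotone in ORF length), a property the tests
exercise directly.

## Positional classification (classify)

Five mutually exclusive classes by precedence:

1. **sense** — ≥ 1 bp exon-to-exon overlap with a coding transcript, same
   strand;
2. **antisense** — any overlap with a coding gene span, opposite strand;
3. **other** — same-strand span overlap without exonic overlap (intronic);
4. **bidirectional** — no gene overlap and a transcription start within
   1,000 bp of a coding gene's TSS in divergent (head-to-head) orientation;
5. **intergenic** — everything else.

The overlap-based classes outrank the proximity-based ones so that a
decision never depends on a window parameter when physical overlap exists.
The 1-kb window is the conventional divergent-promoter distance and is
configurable. TSS of a − strand feature is its last base (0-based `end−1`).
Ties are broken by smallest distance, then lexicographic gene id, making the
assignment deterministic. A lncRNA on a chromosome absent from the
annotation is reported intergenic with infinite distance rather than as an
error. The indexed implementation is verified against an all-pairs
brute-force re-statement of these rules on random layouts, and against the
generator's truth labels (100 % agreement, definitionally).

## Differential expression (diffexpr)

FPKM_ij = count_ij · 10⁹ / (length_i · colsum_j) is used for abundance
reporting and trans-correlation only; testing operates on raw counts with
median-of-ratios size factors (the pseudo-reference is the geometric mean
over samples of transcripts with all-positive counts).

The test is the exact sum-conditioned negative-binomial test: under the
null, the group sums K_A, K_B are NB with means q̄·Σ_A s_j and variances
q̄·Σ s_j + α·q̄²·Σ s_j², and the two-sided p-value is the probability, given
K_A + K_B, of splits no more probable than the observed one. The joint
probabilities are computed in log space and renormalized, so the p-value is
exact up to floating point; the observed-probability comparison uses a
1 + 1e-12 relative guard against ties lost to rounding. At α → 0 (the floor
is 1e-8) the conditional law converges to a binomial, which the tests check
against an independent binomial oracle to 1e-6.

Dispersion: per-transcript method of moments on normalized counts using
within-group variability with the size-factor correction
α̂ = (w − q̄·mean(1/s)) / q̄², followed by a least-squares fit of the
mean-dispersion trend α(q) = a₀ + a₁/q across all transcripts of the
contrast; the fitted value (floored at 1e-8) enters the test. The raw
per-transcript estimate with 3 replicates per group is too noisy to keep
the exact test calibrated — measured type-I at nominal 0.05 is ≈ 0.02 with
total-variance moments (the estimate absorbs the group difference) and
≈ 0.11 with unshared within-group moments — while the fitted trend gives
≈ 0.048 and recovers the simulated dispersion. The unshared estimator
remains available (`dispersion_mode="per_transcript"`), and a fixed
dispersion can be supplied for limit-case analysis. Fewer than 20
transcripts fall back to the raw estimates (no trend to fit).

log₂FC = log₂((mean_B + 0.5)/(mean_A + 0.5)); the 0.5 pseudo-count keeps
zero-mean transcripts finite and is configurable. DE calls are strict:
FDR < 0.05 (Benjamini–Hochberg within contrast) and |log₂FC| > 1; a raw
p-value rule is selectable. No independent filtering is applied — every
transcript is tested. Sample order within groups is canonicalized so the
result is exactly order-invariant; swapping the groups negates log₂FC and
preserves p up to summation order (~1e-7).

The four study contrasts are HP vs LP within each genotype and BR vs NR at
each phosphate level; set bookkeeping (unions, intersections, uniques,
direction partitions) asserts the inclusion–exclusion identity on every
pair it reports.

## Target prediction (targets)

* **cis**: non-overlapping coding genes whose span gap to the lncRNA span is
  ≤ 10 kb, boundary inclusive ("10 kb upstream and downstream" read as a
  closed interval); the score is the gap in bp. Indexed search is verified
  against an all-pairs scan.
* **antisense**: best local alignment of the lncRNA against the reverse
  complement of its overlapped gene's mRNA — match +1, G:U wobble +0.5
  (appearing as (G,A)/(T,C) pairs in complement space), mismatch −1, gap −2
  — normalized by the aligned lncRNA length; a pair is reported at score
  ≥ 0.8 over ≥ 50 aligned nt. This is a declared stand-in for thermodynamic
  RNA–RNA hybridization: nearest-neighbor energy models are out of scope,
  but the scheme is deterministic and its null behaviour is measured
  (random 500-nt pairs at GC 0.35 score < 0.8 in > 99 % of trials; the
  observed null maximum is ≈ 0.26).
* **trans**: Pearson r of log₂(FPKM+1) across all 12 samples for every DE
  lncRNA × mRNA pair, reported at |r| ≥ 0.95 with BH-adjusted
  correlation-test p < 0.05, cis pairs excluded. The stringent threshold
  keeps pair counts sparse at n = 12, where moderate correlations arise
  easily by chance; on default synthetic data (no planted co-expression
  beyond shared condition effects) few or no trans pairs are expected.
  Zero-variance profiles are skipped with a log message.

## miRNA analysis (mirna)

Precursor candidacy is the best ungapped full-length placement of the
mature miRNA or its reverse complement in a lncRNA; identity =
matches/miRNA length and a hit requires identity strictly greater than 0.9
("more than 90 %"), so 19/21 qualifies and 18/21 does not. The search is
strand-symmetric by construction. Local ungapped identity over the mature
sequence was chosen over global alignment because precursors embed the
mature miRNA exactly or near-exactly. Hairpin/secondary-structure
validation of precursors is out of scope.

Target sites are scored at every ungapped placement of the miRNA against
the transcript's complement (antiparallel): mismatch 1.0, G:U 0.5, N
counts as mismatch, all doubled at miRNA positions 2–13 (the 5′ core that
dominates plant target recognition); sites with penalty ≤ 4.0 are reported
with coordinates. The penalty is monotone non-decreasing in mismatches and
the vectorized scan is verified against a per-offset, per-position oracle.

Shared targets are mRNAs hit by at least one miRNA of the ten
phosphate-related families (miR399, miR827, miR395, miR319, miR156, miR159,
miR166, miR169, miR398, miR447 — family membership by substring of the
miRNA id) and by at least one DE lncRNA, with full provenance retained.

## Enrichment, networks, qPCR

Term enrichment is the upper-tail hypergeometric p per term, BH-adjusted
within each category (BP/MF/CC/KEGG); the universe defaults to all genes
with ≥ 1 annotation (configurable). Significance is reported both at raw
P < 0.05 and at q < 0.05, since reasonable analyses use either. No GO
ancestor propagation is performed. The implementation is checked against
exhaustive subset enumeration for every universe of size ≤ 12 to 1e-12.

The tripartite network places each shared mRNA with its targeting lncRNAs
(edges typed by target mode) and miRNAs (`mirna_target` edges); every mRNA
node therefore has both a lncRNA and a miRNA in-edge. The interest network
keeps every lncRNA with at least one labelled (TF / P_related / hormone)
target together with *all* targets of those lncRNAs, labelled or not.
Labels are user input; labels for genes that never occur as targets are
warned about and ignored. Networks are data products (GraphML with node and
edge attributes, TSV edge lists), not rendered figures.

qPCR relative quantification averages technical replicates to one Ct per
biological replicate first, takes ΔCt against the reference gene within the
same (condition, replicate), and ΔΔCt against the calibrator condition's
mean; RQ = 2^−ΔΔCt. Averaging before exponentiation is standard ΔΔCt
practice. The identities RQ(calibrator) = 1, plate-offset invariance and
RQ(a→b)·RQ(b→a) = 1 hold exactly and are asserted. The calibrator is the HP
condition of the genotype carrying the planted treatment effect, matching
the LP/HP fold-change framing. Amplification efficiency is assumed to be 2
(no efficiency correction). Concordance is the OLS of qPCR log₂ fold
changes on sequencing log₂ fold changes.

## The synthetic data generator (syndata)

Defaults emulate the study conditions: 12 libraries named
`HP-NR-1 … LP-BR-3` (2 genotypes × 2 phosphate levels × 3 replicates), a
4 × 600-kb genome with 200 non-overlapping coding genes (1–7 exons, CDS
codons from the shared codon table, UTRs and intergenic space at GC 0.35),
and 595 lncRNAs in the five positional classes at the study's proportions
scaled by 1/7 (409 intergenic, 71 antisense, 65 bidirectional, 33 other,
17 sense) — enough for class-level statistics while keeping the default
pipeline run under ten seconds. lncRNA lengths are log-normal
(median ≈ 480 nt, σ = 0.7) truncated to [201, 4000] nt, putting ≈ 98 %
below 2 kb; ~84 % are single-exon.

Placement satisfies the classifier's definitions by construction: sense
lncRNAs straddle an intron/exon junction on the gene's strand, antisense
and "other" lncRNAs sit inside introns (opposite/same strand),
bidirectional lncRNAs start 3–201 bp outside a divergent TSS, and
intergenic lncRNAs keep more than the bidirectional window from every gene
span. Genic lncRNAs are transcribed off the genome rather than stamped over
gene sequence, so the chromosome FASTA, transcript FASTA and mRNA sequences
never disagree; that also means genic lncRNA sequences are background-like
(intronic) rather than independently drawn, which is the realistic case.

Counts are NB(mean = s_j·μ_i·2^effect, dispersion α = 0.05) with size
factors log-uniform in [0.5, 2] (so normalization is exercised
non-trivially) and baselines log-normal (median 150, σ = 1.2; an optional
truncation floor realises "base mean ≥ x" conditions). Planted effects have
magnitude exactly log₂FC = 2: treatment effects apply to the LP samples of
one genotype (BR), genotype effects to the NR samples, and a transcript
carries at most one of the two, so every non-null true contrast effect has
the planted magnitude — including the induced effect a BR-only treatment
response shows in the LP-level genotype comparison. At α = 0 the sampler
switches to Poisson.

miRNAs (10 by default, named for the phosphate-related families) are 20–24
nt; precursors are embedded in single-exon intergenic/bidirectional lncRNAs
with at most the number of mismatches that keeps identity above 90 %;
perfect complementary target sites are embedded in the 3′-UTR tail of
mRNAs lying within 10 kb of a DE lncRNA, which makes the nine planted
shared targets recoverable by the cis → miRNA → intersection route. After
every embedding the genome is mutated and the affected record re-extracted,
preserving sequence consistency. Ct panels follow
Ct = 32 − log₂(normalized expression) + N(0, 0.2) per technical replicate
(3 × 3 per condition), with the tubulin control at a constant normalized
level.

What the generator does **not** emulate: sequencing reads (the pipeline
starts from assembled models), assembly artefacts and fragmented
transcripts, real soybean sequence content and repeat structure,
mean-dependent dispersion trends, correlated co-expression modules, GC or
length biases in counting, and hairpin structure around planted precursors.
Passing tests therefore demonstrate the correctness of the implemented
rules and the statistical calibration of the test under NB sampling — not
performance on real libraries, where dispersion trends, assembly noise and
annotation incompleteness dominate.

## Reproducibility and problem sizes

Every generator stage derives its RNG from (seed, stage index), so outputs
are independent of call interleaving and byte-identical across reruns; the
pipeline manifest records the config hash, seed and a sha256 per output
file, and end-to-end determinism is asserted by comparing manifests of two
fresh runs. Statistical checks run at the sizes stated with them: 5,000
null transcripts for type-I calibration, 2,000 transcripts with 10 %
planted DE for recovery, 100–200 random layouts for the oracle
equivalences, 1,000 random pairs for the duplex null — sizes chosen so the
whole suite completes in well under a minute per check while the binomial
error on the measured rates stays far from the asserted bounds.

## Known limitations

* The exact NB test recomputes the full conditional distribution per
  transcript; at extreme depths (group sums ≫ 10⁵) it becomes the dominant
  cost. Desk-scale inputs are unaffected.
* The duplex score is an alignment heuristic, not a free-energy model;
  its 0.8/50-nt threshold was chosen for a near-zero null rate, not
  calibrated against hybridization data.
* Trans-target detection at n = 12 with |r| ≥ 0.95 has low power for
  anything but near-deterministic co-expression; this is a deliberate
  sparsity choice.
* Enrichment ignores the GO DAG; parent terms are not credited.
* The qPCR model assumes perfect amplification efficiency and
  expression-independent Ct noise.
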