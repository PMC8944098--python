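# Methods

This note documents the generative model behind the synthetic data, the
algorithms in each pipeline stage, the numerical choices that matter, and
what the validation studies do and do not establish.

## The export-homeostasis model

Each gene g has a transcription rate σ_g (molecules/h), a first-order decay
rate δ_g (/h) and a first-order export rate ε_g (/h) describing loss of
transcripts from the cell into extracellular vesicles. The cellular copy
number obeys dc/dt = σ − (δ + ε)c, so the steady state is c* = σ/(δ + ε)
(verified against direct ODE integration to 1e-6 relative error in the test
suite). EV output flux is ε·c*. Both compartments are observed
compositionally — sequencing measures proportions, not absolute flux — so
truth tables carry cell and EV fractions and the per-gene log2 packaging
log2(ev_frac / cell_frac).

Export is feature-driven on a log2 scale:

    log2(ε_g/δ_g) = β0 + β_len·z(log2 L_g) + β_exon·z(epk_g) + β_gc·z(gc_g)
                  + β_motif·(motif_g − mean) + β_hl·z(log2 t½_g) + noise

with z(·) a z-score over genes. Defaults: β0 = −3.5 (median export accounts
for ~9% of transcript removal — large enough that blocking export visibly
raises cellular abundance, which is the premise of the inhibitor analysis),
β_len = −0.5, β_exon = +0.3, β_gc = +0.2, β_motif = +1.0, β_hl = +0.3,
noise sd 0.5. The half-life coefficient makes export propensity increase
with transcript stability, so the enriched set has longer half-lives — a
qualitative property of the real system the package is designed to detect.

Conditions:

- **basal** — the steady state above.
- **treated** — a fraction (default 0.3) of genes receives a log2
  transcription shift drawn uniformly from ±[0.5, 2]; packaging couples to
  the shift as Δlog2 packaging = −λ·Δlog2 σ + Gaussian noise (sd 0.25).
  λ ≥ 0 is the coupling parameter (default 0.3). The literature motivating
  this model gives the coupling only by sign, so λ is a free simulation
  parameter and recovery is assessed against whatever value was planted.
- **inhibitor** — ε → (1 − i)·ε for an affected subset (default: all genes,
  modelling a global block of vesicle biogenesis), i ∈ [0, 1], default 0.8.
  Cellular abundance is recomputed from the closed form; the per-gene gain
  log2((δ+ε)/(δ+(1−i)ε)) grows with ε/δ, so strongly exported transcripts
  accumulate most — the mechanism the inhibitor contrast detects.
- **spike mode** — for calibration studies the feature machinery is
  bypassed and log2 ε is set directly: 10% of genes get a planted
  |log2 packaging| offset in [1.5, 2.5] with random sign, the rest are
  exactly null. This gives unambiguous truth labels for
  sensitivity/false-discovery measurements.

## Synthetic transcriptome and reads

`build_transcriptome` lays one chromosome: genes in sequence with random
intergenic gaps, one transcript per gene, exon counts from a per-kb density
draw, per-gene GC (sequences i.i.d. at that GC), mRNA genes with a
5′UTR/CDS/3′UTR partition (defaults 10%/60%/30%). A planted 8-nt GGAG-core
motif (`TAGGAGGC`) appears in ~30% of genes (1–3 copies, preferentially in
the 3′UTR of mRNAs); CLIP-like peaks are emitted as BED intervals at the
first planted instance of each gene, so peak-overlap enrichment has a
ground truth. Antisense lncRNAs are carved into long introns of
protein-coding hosts on the opposite strand (the genome bases there are
overwritten with the reverse complement of the lncRNA), which makes
span-overlap pairing meaningful; lincRNAs are intergenic, so
nearest-neighbor pairing works directly. A small rRNA set (3 sequences,
1.2–5.2 kb, GC 0.55) is written separately for the contamination screen.
Everything is deterministic for a fixed seed (byte-identical files).

`simulate_reads` draws unique molecules multinomially with probability ∝
abundance × effective length, places fragments uniformly, assigns each
molecule a random 8-nt UMI, replicates it Geometric(mean d) times (PCR
duplicates share UMI and position exactly; positional jitter is off by
default), applies substitution errors at rate e (default 0.002), appends
declared fractions of rRNA-derived (5%) and low-complexity (2%) junk reads,
and prefixes every 75-nt read with a fixed 5-nt adapter. Three replicates
per condition/compartment by default. UMI collisions are allowed and left
to the dedup stage.

What the generator does *not* emulate: codon structure, splicing signals,
positional/GC coverage bias, fragment-length variation within a read,
indels, quality-score structure, batch effects. Passing tests therefore
demonstrate algorithmic correctness and statistical calibration under the
stated model, not robustness to every artifact of real libraries.

### Study scales

The read-level path (FASTQ → trim → filters → alignment → dedup → EM) is
exercised end-to-end at desk scale (≤ 300 genes, ≤ 60k reads per sample).
The statistical studies (calibration, coupling recovery, inhibitor and
feature contrasts) draw deduplicated molecule counts directly from the
truth tables as gamma-Poisson (NB, dispersion 0.05) at depth 1e6 with 3
replicates and 2000 genes — the count-level image of the read pipeline,
which the suite separately shows recovers true molecule counts exactly up
to UMI-collision noise when errors and jitter are off.

## Pipeline algorithms

**Trimming.** First 5 nt removed (adapter); reads shorter than
trim + 20 nt discarded.

**Low-complexity filter.** Score = 100·H/log(min(64, L−2)) with H the
Shannon entropy (nats) of the overlapping trinucleotide distribution;
reads below 70 are dropped. A dinucleotide repeat scores ≈ 18, a
homopolymer 0, i.i.d. random 70-mers ≈ 95.

**rRNA screen.** Exact 25-mer membership against both strands of the rRNA
reference; any shared k-mer flags the read. At zero error this removes
> 99% of rRNA-derived reads while leaving transcript reads untouched.

**Pseudo-alignment.** Exact 21-mer index over transcript sense strands.
Seeds are taken every 4 nt of the read; a transcript is compatible when
≥ 2 seeds agree on one diagonal (transcript position − read offset).
Primary position: most seed hits, ties to the smaller inferred 5′ offset,
then the lexicographically smaller transcript id. No indel tolerance —
the generator produces none, and real indel-tolerant alignment is out of
scope.

**UMI dedup.** Within each (sample, transcript, UMI) group, reads sorted
by 5′ offset are clustered greedily: a read joins the open cluster iff its
offset is within ceil(read_length/2) of the cluster's first read (38 bp
for 75-nt reads). The cluster anchor (first by offset, ties by read id) is
retained, which makes the operation idempotent; retaining any other member
would let a survivor's offset drift into the next cluster's window.
Duplicate groups are defined within a single transcript (the primary
assignment); cross-transcript grouping is ill-defined for multi-mappers.
Only exact UMI matches merge — no 1-mismatch collapsing.

**Equivalence-class EM.** Each read contributes 1 to the class keyed by
its compatible transcript set. The EM variable is the read-share vector α
(the probability a sequenced read comes from transcript t); each class's
count is allocated ∝ α over its members, and iteration stops when
max|Δα| < 1e-8 (or 1000 iterations, with a logged warning). The class
multinomial log-likelihood is non-decreasing across iterations and the
fixed point matches brute-force likelihood maximization on 3-transcript
toys. Estimated counts are the final responsibilities;
TPM_t = 1e6·(est_t/ℓ̃_t)/Σ_u(est_u/ℓ̃_u) with effective length
ℓ̃ = max(1, L − fragment mean + 1). The fragment-length mean is the
simulation's true value when known, else a parameter (default 200).

**Gene aggregation and detection.** Transcript est_counts/TPM sum to gene
level; a gene is detected in a sample group when its mean TPM over the
group's replicates is ≥ 1.

**Coverage extent.** Per replicate pair, cell alignments are subsampled
uniformly without replacement (seeded) to the paired EV replicate's mapped
count. Per gene, on the primary transcript: the statistic is
(3′-most read end − 5′-most read start, clipped to the region) divided by
the region length — the CDS for mRNA, the whole transcript for lncRNA —
averaged over replicates. Reads count toward the gene of their primary
transcript only, avoiding double-counting of multi-mappers. "Read extent"
(start to end) is used rather than read starts alone. Depth matching is
per replicate pair rather than in aggregate — the finer-grained of the two
plausible readings.

**Differential abundance.** Median-of-ratios size factors (computed over
genes positive in all samples, rescaled to geometric mean 1). Per gene:
normalized group means with pseudo-count 0.5 give the log2 fold
difference; NB dispersion comes from within-group moments,
α = Σ(v−m)/Σm² per gene, clipped to [1e-8, 10] and floored at the pooled
ratio-of-sums estimate across all genes. The floor matters: per-gene
moment estimates at n = 3 scatter widely and their chance underestimates
would make the Wald test anticonservative, while the pooled estimate is
stable and nearly unbiased; a global floor is not a mean-dispersion trend
fit (deliberately out of scope). The Wald statistic log2fd/se — with se
from the delta method on Var(K/s) = μ/s + αμ² — is referred to the
standard normal. Significance: BH-adjusted p < 0.1 over the tested
universe (genes passing detection, by default in the cell compartment).
No LFC shrinkage, no independent filtering; outputs will not numerically
match heavier DE engines, and validity is established by the calibration
and recovery studies instead. mRNA and lncRNA are tested separately by
default, with a combined mode for pooled analyses.

**Packaging change and contrasts.** ΔP = log2fd(EV vs cell, experimental)
− log2fd(EV vs cell, basal), using raw (unshrunken) fold differences, over
the gene intersection. The anticorrelation analysis reports Pearson r/p of
ΔP against the cellular log2 fold change plus the least-squares slope
(whose negative recovers λ, attenuated slightly by measurement noise in
the regressor). The distribution-shift analysis compares EV-vs-cell
log2fd distributions between conditions within the cell-up and cell-down
gene sets (Welch test, medians). The inhibitor contrast Welch-tests the
cellular log2 fold changes of basal EV-enriched genes against the other
detected genes.

**Features.** All per-gene features come from the primary transcript — the
longest, ties to the smallest transcript id (external principal-isoform
annotations don't exist for synthetic genomes, and length is the standard
fallback). ARE density counts possibly-overlapping AUUUA pentamers per kb
of the UTR (the minimal canonical ARE; the motif string is configurable
since richer ARE definitions exist); regions shorter than the pentamer
score 0. Half-life is fit by least squares of ln(abundance) on time over
positive observations (≥ 3 required, including t = 0 in the design);
t½ = ln2/(−slope) when the slope is negative, undefined ("stable")
otherwise. The noisy-recovery study reports the median absolute relative
error over genes with TPM ≥ 10, the robust summary of typical accuracy:
individual low-abundance genes near the threshold have counting noise
that no estimator can beat.

**Motif scanning.** Position probability matrices (MEME minimal format
in/out; RNA alphabets map U→T at load) are scored as log2 likelihood
ratios against the background. Scores are quantized to a 1/1000 grid and
the exact null distribution of window scores under the background is
computed by dynamic programming over positions; the hit threshold is the
smallest score with null tail probability ≤ 1e-4. For motifs too narrow
for that p (a w-mer's best match has null probability ≥ 4^−w) the
threshold clamps to the maximum achievable score, so an exact consensus
match still registers. Scanning is sense-strand only (RNA is
single-stranded) and hit calls are presence/absence of any passing window.
Enrichment is a one-sided Fisher test of hit rates in the EV-enriched set
against the "unchanged" background (default: tested genes with padj ≥ 0.5,
i.e., clearly non-differential; configurable), BH-corrected across motifs.
The shipped motif set (SYN_*) consists of synthetic consensus-based
matrices matching the generator's planted motif family plus controls —
stand-ins, not curated RBP matrices.

**CLIP overlap.** A gene is bound when ≥ 1 peak overlaps its genomic span
(half-open intervals; abutting peaks do not bind). The span default —
rather than exons — reflects that crosslinking peaks are genomic and often
intronic; an exonic-only mode exists. Enrichment is Fisher's exact test of
bound fractions, EV-enriched versus other expressed genes.

**lncRNA pairing.** Antisense lncRNAs pair with the protein-coding gene
they overlap on the opposite strand (largest overlap wins, no minimum
overlap length required); lincRNAs pair with the nearest protein-coding
gene by genomic gap (0 if overlapping). Ties break to the smallest gene
id. Pearson correlation over paired EV-vs-cell log2 fold differences;
under the generator, partners are enriched independently, so the expected
correlation is zero.

## Numerical choices and degenerate inputs

- Coordinates: 0-based half-open everywhere internally; GTF converts at
  the parser boundary. Sequences stored as DNA, sense strand.
- Welch's test: both groups constant with equal means → p = 1 by
  convention; constant with unequal means, or a single constant group, is
  an error. Feature comparisons skip constant fields.
- BH adjustment preserves input order and is monotone in p-rank. It is
  *not* idempotent (re-adjusting adjusted values inflates them); no stage
  relies on idempotence.
- Fisher's exact test matches exact hypergeometric enumeration for all
  2×2 tables with margins ≤ 12 (verified exhaustively).
- EM: an all-zero class system yields zero counts; classes referencing
  unknown transcripts are ignored.
- Dedup window boundary is inclusive: offsets exactly 38 apart merge,
  40 apart do not.
- PWM scanning treats non-ACGT letters as worse than any mismatch; a
  sequence shorter than the motif is a non-hit, not an error.
- Size factors require at least one gene positive in all samples.
- The acceptance script reduces its seed modulo 2^20 so all derived seeds
  stay far below 2^31.

## Known limitations

- The pseudo-aligner is exact-match seed based: heavily mutated reads
  (≫ 2% substitution) or indel-bearing reads go unmapped.
- The NB test's normal Wald reference with a pooled dispersion floor is
  calibrated in the simulated regimes tested (FDP ≤ 0.12 at nominal 0.1);
  heavy-tailed real data with gene-specific dispersion far above the pool
  may need the per-gene estimate cap raised.
- Compositional truth means absolute export flux is unidentifiable; all
  packaging statements are relative, matching what sequencing can see.
- The coupling slope recovered from data underestimates λ by a few percent
  (regression attenuation from noise in the cellular fold-change
  regressor); recovery tolerances account for this.
- Motif hit calling is presence/absence at a single threshold; no
  accounting for sequence length differences between gene sets (the
  planted-motif studies use length-matched backgrounds implicitly, real
  analyses may want a length covariate).
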